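# English glosses for the bundled Chinese seeds (word<TAB>gloss<TAB>polarity).
抑郁	depression	dep
崩溃	collapse	dep
压力	stress	dep
自杀	suicide	dep
绝食	apastia	dep
焦躁	anxious	dep
伤心	sad	dep
疲惫	tired	dep
死亡	death	dep
孤独	lonely	dep
失眠	insomnia	dep
难受	bad	dep
绝望	desperate	dep
放弃	give up	dep
卑微	low	dep
离开	leave	dep
恐惧	fear	dep
危险	danger	dep
封闭	close	dep
敏感	sensitive	dep
茫然	lost	dep
阴影	shadow	dep
摧毁	destroy	dep
怀疑	suspect	dep
崩塌	crash	dep
黑暗	dark	dep
无助	helpless	dep
愧疚	guilt	dep
负面	negative	dep
沮丧	frustration	dep
紧张	nervous	dep
忧郁	melancholy	dep
废物	rubbish	dep
跳楼	jump	dep
遗忘	forget	dep
再见	goodbye	dep
割腕	cut wrist	dep
边缘	edge	dep
阴霾	haze	dep
抗抑郁药	antidepressant	dep
稳定	stability	nondep
舒服	comfort	nondep
高兴	happy	nondep
幸福	happiness	nondep
顺利	successful	nondep
自信	confidence	nondep
阳光	sunshine	nondep
奋斗	struggle	nondep
积极	positive	nondep
勇敢	brave	nondep
享受	enjoy	nondep
平安	peace	nondep
热情	enthusiasm	nondep
健康	healthy	nondep
满意	satisfied	nondep
活力	active	nondep
成长	grow up	nondep
骄傲	pride	nondep
优秀	good	nondep
敬佩	admire	nondep
完美	perfect	nondep
称赞	praise	nondep
强大	strong	nondep
珍贵	precious	nondep
进步	progress	nondep
庆贺	congratulate	nondep
关爱	love	nondep
欢迎	welcome	nondep
强壮	robust	nondep
善良	kindness	nondep
认真	earnest	nondep
同意	agree	nondep
支持	support	nondep
奖励	award	nondep
优势	advantage	nondep
划算	good deal	nondep
发展	develop	nondep
温暖	warm	nondep
鲜艳	bright colored	nondep
明白	understand	nondep
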