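# Curated depression-domain seeds: 40 depressive (dep) + 40 nondepressive (nondep).
# Chinese microblog vocabulary; English glosses in seeds_zh_gloss.tsv.
抑郁	dep
崩溃	dep
压力	dep
自杀	dep
绝食	dep
焦躁	dep
伤心	dep
疲惫	dep
死亡	dep
孤独	dep
失眠	dep
难受	dep
绝望	dep
放弃	dep
卑微	dep
离开	dep
恐惧	dep
危险	dep
封闭	dep
敏感	dep
茫然	dep
阴影	dep
摧毁	dep
怀疑	dep
崩塌	dep
黑暗	dep
无助	dep
愧疚	dep
负面	dep
沮丧	dep
紧张	dep
忧郁	dep
废物	dep
跳楼	dep
遗忘	dep
再见	dep
割腕	dep
边缘	dep
阴霾	dep
抗抑郁药	dep
稳定	nondep
舒服	nondep
高兴	nondep
幸福	nondep
顺利	nondep
自信	nondep
阳光	nondep
奋斗	nondep
积极	nondep
勇敢	nondep
享受	nondep
平安	nondep
热情	nondep
健康	nondep
满意	nondep
活力	nondep
成长	nondep
骄傲	nondep
优秀	nondep
敬佩	nondep
完美	nondep
称赞	nondep
强大	nondep
珍贵	nondep
进步	nondep
庆贺	nondep
关爱	nondep
欢迎	nondep
强壮	nondep
善良	nondep
认真	nondep
同意	nondep
支持	nondep
奖励	nondep
优势	nondep
划算	nondep
发展	nondep
温暖	nondep
鲜艳	nondep
明白	nondep
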