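# Versioned synthetic benchmark parameter sets.
#
# "lexicon": the planted-lexicon recovery benchmark for comparing the
# construction methods.  Strong enrichment and well-separated embedding
# clusters (expected within-cluster cosine ~0.8).
#
# "detection": the user-level screening benchmark.  Weak enrichment so the
# per-user signal is noisy and classifier differences are visible; more
# users, fewer tokens each.
lexicon:
  n_background: 100
  n_dep_words: 30
  n_nondep_words: 30
  n_users_per_group: 50
  posts_per_user: 20
  tokens_per_post: 15
  enrichment: 6.0
  embed_dim: 50
  cluster_separation: 2.8284271247461903
  noise_sd: 0.1
  rng_seed: 0

detection:
  n_background: 100
  n_dep_words: 30
  n_nondep_words: 30
  n_users_per_group: 100
  posts_per_user: 10
  tokens_per_post: 20
  enrichment: 1.2
  embed_dim: 50
  cluster_separation: 2.8284271247461903
  noise_sd: 0.1
  rng_seed: 0
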