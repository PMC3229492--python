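"""Robustness of the consistency MSA to structurally unrelated sequences.

Aligns a 4-member simulated family with and without two unrelated sequences
injected, for both the synonym consistency scheme and the BLOSUM62
progressive baseline, and reports how much each method's accuracy on the
original members moves.
"""

from synaln.protocols import outlier_robustness_study

res = outlier_robustness_study(n_seeds=5, base_seed=2)
print("mean evaluated-member Q-score (5 seeds):")
print(f"  synonym MSA   clean {sum(res.q_synonym_clean)/5:6.2f}%"
      f"   with outliers {sum(res.q_synonym_outliers)/5:6.2f}%"
      f"   change {res.synonym_mean_change:+.2f}")
print(f"  BLOSUM62 MSA  clean {sum(res.q_blosum_clean)/5:6.2f}%"
      f"   with outliers {sum(res.q_blosum_outliers)/5:6.2f}%"
      f"   change {res.blosum_mean_change:+.2f}")
print("(smaller |change| = less disturbed by unrelated sequences in the job)")
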