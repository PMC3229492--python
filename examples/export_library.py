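"""Export synonym-word scores as a T-Coffee residue-pair library.

The normalized score matrix of every target pair becomes a TC_LIB_FORMAT_01
block, consumable either by genuine T-Coffee or by the package's internal
consistency aligner.
"""

from synaln import (
    build_library,
    extract_synonyms,
    normalize_scores,
    raw_pair_scores,
    simulate_family,
    write_tc_lib,
)

sim = simulate_family(seed=7, ancestor_length=80, n_homologs=8)
s, t = sim.targets
ts = extract_synonyms(sim.homolog_sets[s.id], word_length=4)
tt = extract_synonyms(sim.homolog_sets[t.id], word_length=4)
raw = raw_pair_scores(ts, tt)
norm = normalize_scores(raw)
print(f"alignable residue pairs: {len(norm.cells)}  (N = {norm.n_groups})")

lib = build_library([(s, t, norm)])
write_tc_lib(lib, "family.tc_lib")
head = "\n".join(open("family.tc_lib").read().splitlines()[:6])
print("library head:")
print(head)
print("(each entry line is: residue_of_S residue_of_T weight, 1-based)")
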