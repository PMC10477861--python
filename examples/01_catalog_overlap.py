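"""Catalog arithmetic: deduplication, set overlap, recall, screen summary.

Builds two small peptide catalogs (think: an anticancer-peptide database
and an antimicrobial-peptide database), merges them with exact-sequence
deduplication, reports how much they overlap, and summarizes a toy
cell-line inhibition screen.
"""

import pandas as pd

from acpmine import (
    PeptideCatalog,
    PeptideRecord,
    deduplicate_union,
    filter_natural_aa,
    overlap_stats,
    recall_rate,
    summarize_screen,
)


def cat(name, seqs):
    return PeptideCatalog(
        records=[PeptideRecord(id=f"{name}{i+1}", sequence=s, source_db=name)
                 for i, s in enumerate(seqs)],
        name=name)


acps = cat("acp", ["FLFKLIPKAIKGLIKAFK", "GLFDIIKKIAESF", "KWKLFKKIEKVGQNIR",
                   "GIGKFLHSAKKFGKAFVGEIMNS", "MKXTP"])       # one non-natural
amps = cat("amp", ["GLFDIIKKIAESF", "KWKLFKKIEKVGQNIR", "FLPIIAKLLSGLL"])

acps, removed = filter_natural_aa(acps)
print(f"removed for non-natural residues: {removed}")

union = deduplicate_union(acps, amps)
ov = overlap_stats(acps, amps)
print(f"union holds {len(union)} unique sequences; "
      f"{ov.n_overlap} shared = {ov.overlap_pct}% of the union")
# the overlap percentage is the share of all distinct peptides that carry
# both activities — high overlap motivates reusing AMP predictors for ACPs

print(f"recall of a 1279-peptide reference pool at 1033 hits: "
      f"{recall_rate(1033, 1279)}%")

# survival (%) of two cell lines after treatment with each peptide
survival = pd.DataFrame(
    [[70, 95], [85, 79], [99, 100], [100, 98]],
    index=["acp1", "acp2", "acp3", "acp4"], columns=["HT29", "HCT116"])
screen = summarize_screen(survival, inhibition_threshold_pct=20)
print(f"screen: {screen.n_active}/{screen.n_peptides} peptides "
      f"({screen.active_pct}%) inhibit >=20% in at least one cell line")
print("hits per peptide:", {k: int(v) for k, v in screen.per_peptide_hits.items()})
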