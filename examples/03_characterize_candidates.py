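"""Sequence novelty and physicochemistry of a candidate set.

Compares mined candidates against a reference peptide set: global affine-
gap alignment identities (are the candidates novel?), GRAVY hydropathy and
net charge (are they more hydrophilic / differently charged?).
"""

from acpmine import (
    compare_identity_distributions,
    contrast_sets,
    generate_catalog,
    gravy,
    identity_distribution,
    needleman_wunsch,
    net_charge,
)

candidates = generate_catalog(8, (31, 50), seed=5, id_prefix="cand")
reference = generate_catalog(8, (10, 25), seed=6, id_prefix="ref")

res = needleman_wunsch(candidates.records[0].sequence,
                       reference.records[0].sequence)
print(f"example alignment: score {res.score}, identity "
      f"{res.identity_pct:.1f}% over {res.alignment_length} columns")

within_ref = identity_distribution(reference, within=True, thresholds=(80.0,))
cross = identity_distribution(candidates, reference, thresholds=(30.0, 80.0))
print(f"reference-vs-reference mean identity: "
      f"{sum(within_ref.pair_identities)/len(within_ref.pair_identities):.1f}%")
print(f"candidate-vs-reference mean identity: "
      f"{sum(cross.pair_identities)/len(cross.pair_identities):.1f}%")
print(f"cross pairs above 30% identity: {cross.fraction_over[30.0]:.2f} "
      f"(low values = novel candidates)")

contrast = compare_identity_distributions(within_ref, cross)
print(f"one-sided Welch t on identities: t={contrast.statistic:.2f}, "
      f"p={contrast.p_value:.2e}, {contrast.direction}")

g_cand = [gravy(r.sequence) for r in candidates]
g_ref = [gravy(r.sequence) for r in reference]
c = contrast_sets(g_cand, g_ref, sidedness="two-sided")
print(f"GRAVY contrast (candidates vs reference): t={c.statistic:.2f}, "
      f"p={c.p_value:.3f}; negative GRAVY = hydrophilic")
print("net charges of candidates:",
      [net_charge(r.sequence) for r in candidates])
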