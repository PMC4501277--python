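"""Directional inclusion analysis between diseases.

For each qualifying disease pair the inclusion index tau = |X∩Y|/|X| is
computed in both directions; tau = 1 means one disease's gene set is a
subset of the other's.  The example summarizes tau within ICD-10-CM
chapters and then looks at the Neoplasms chapter (C00-D49) as disease X
versus disease Y — the directionality view.
"""

from diseasome import (
    SyntheticConfig,
    all_directed_inclusions,
    build_bipartite,
    disease_profiles,
    focal_directionality,
    generate_study,
    load_default_chapters,
    normalize_symbols,
    project_disease_pairs,
    same_category_summary,
)

study = generate_study(SyntheticConfig(seed=42))
normed, _ = normalize_symbols(study.disease_gene, study.hgnc)
profiles = disease_profiles(build_bipartite(normed))
pairs = project_disease_pairs(profiles)
records = all_directed_inclusions(profiles, pairs)
print(f"{len(pairs)} gene-sharing pairs -> {len(records)} directed records")

n_subsets = sum(1 for r in records if r.tau == 1)
print(f"records with tau = 1 (subset relations): {n_subsets}")
print(f"planted subset pairs in this study: {len(study.truth.subset_pairs)}")

chapters = load_default_chapters()
print("\nSame-chapter inclusion (median tau per chapter):")
for s in same_category_summary(records, chapters):
    print(f"  {s.group}: n={s.n:4d}  median tau={s.median:.3f}  IQR=[{s.q1:.3f}, {s.q3:.3f}]")

fd = focal_directionality(records, "C00-D49", chapters)
print("\nNeoplasms (C00-D49) against other chapters:")
for role, s in (("as disease X", fd.as_X), ("as disease Y", fd.as_Y)):
    if s is not None:
        print(f"  {role}: n={s.n:4d}  median tau={s.median:.3f}")
print(
    "A higher median as Y than as X would mean neoplasms tend to include "
    "other diseases' genes rather than be included by them."
)
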