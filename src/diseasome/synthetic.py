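"""Seeded synthetic-study generator with planted ground truth.

Emits the four mapping tables the pipeline consumes — a gene-symbol
authority, a disease-gene map, a gene-pathway map and a chapter table —
with three kinds of planted statistical structure:

* chapter-clustered gene sharing: same-chapter diseases draw genes from a
  shared chapter pool with probability ``p_within``, cross-chapter pools
  with ``p_between`` (< p_within), the global pool otherwise;
* subset pairs: for each planted (X, Y), Y's gene set is X's plus at
  least one extra gene, so tau_{x->y} = 1 and tau_{y->x} < 1;
* enriched candidate genes: genes absent from the disease-gene map whose
  pathway sets cover ``planted_overlap`` of one target disease's pathway
  profile, plus uniformly-drawn background candidates.

A fraction ``alias_rate`` of genes are written into the disease-gene
table under a previous/alias symbol so that HGNC normalization is
exercised end-to-end.  Everything is driven by a single integer seed and
all iteration orders are sorted, so the emitted tables are byte-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .chapters import Chapter, codes_in_chapter, load_default_chapters
from .errors import ConfigError, IntegrityError
from .io import write_table
from .model import (
    DiseaseGeneAssociation,
    GenePathwayAssociation,
    GeneSymbol,
    GroundTruth,
    HgncRecord,
    IcdCode,
    PathwayId,
    Prediction,
)
from .network import build_tripartite, disease_pathway_profiles


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study; defaults give a small but structured study."""

    seed: int = 0
    n_chapters: int = 21
    codes_per_chapter: int = 10
    n_genes: int = 800
    genes_per_disease: tuple[int, int] = (2, 10)
    p_within: float = 0.3
    p_between: float = 0.02
    n_subset_pairs: int = 10
    n_pathways: int = 300
    pathways_per_gene: tuple[int, int] = (1, 6)
    n_planted_enriched: int = 20
    planted_overlap: float = 0.8
    alias_rate: float = 0.2
    n_background_candidates: int = 200

    def validate(self) -> None:
        lo_g, hi_g = self.genes_per_disease
        lo_p, hi_p = self.pathways_per_gene
        checks = [
            (1 <= self.n_chapters <= 21, "n_chapters must be in 1..21"),
            (self.codes_per_chapter >= 1, "codes_per_chapter must be >= 1"),
            (self.n_genes >= 1, "n_genes must be >= 1"),
            (1 <= lo_g <= hi_g <= self.n_genes, "genes_per_disease out of range"),
            (1 <= lo_p <= hi_p <= self.n_pathways, "pathways_per_gene out of range"),
            (self.p_within > self.p_between >= 0, "requires p_within > p_between >= 0"),
            (self.p_within + self.p_between <= 1.0, "p_within + p_between must be <= 1"),
            (0 < self.planted_overlap <= 1.0, "planted_overlap must be in (0, 1]"),
            (0.0 <= self.alias_rate <= 1.0, "alias_rate must be in [0, 1]"),
            (self.n_subset_pairs >= 0, "n_subset_pairs must be >= 0"),
            (self.n_planted_enriched >= 0, "n_planted_enriched must be >= 0"),
            (self.n_background_candidates >= 0, "n_background_candidates must be >= 0"),
            (
                2 * self.n_subset_pairs <= self.n_chapters * self.codes_per_chapter,
                "not enough disease codes for the requested subset pairs",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


@dataclass
class SyntheticStudy:
    """The four emitted tables plus machine-readable ground truth."""

    config: SyntheticConfig
    chapters: list[Chapter]
    hgnc: list[HgncRecord]
    disease_gene: list[DiseaseGeneAssociation]
    gene_pathway: list[GenePathwayAssociation]
    truth: GroundTruth

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.hgnc, outdir / "hgnc.tsv", "hgnc")
        write_table(self.disease_gene, outdir / "disease_gene.tsv", "disease_gene")
        write_table(self.gene_pathway, outdir / "gene_pathway.tsv", "gene_pathway")
        write_table(self.chapters, outdir / "chapters.tsv", "chapters")
        (outdir / "ground_truth.json").write_text(self.truth.to_json(indent=2) + "\n")


def _sample_distinct(rng: np.random.Generator, items: Sequence, k: int) -> list:
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in idx]


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate one study deterministically from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chapters = list(load_default_chapters())[: config.n_chapters]

    # Disease codes per chapter, drawn inside each real ICD range so the
    # chapter-assignment logic (including the O9A tail) is exercised.
    codes: list[IcdCode] = []
    chapter_of_code: dict[IcdCode, str] = {}
    for ch in chapters:
        space = codes_in_chapter(ch)
        if config.codes_per_chapter > len(space):
            # Top up from the alphanumeric-suffix space when digit codes run out.
            extra = [c for c in codes_in_chapter(ch, extended=True) if c not in space]
            need = config.codes_per_chapter - len(space)
            if need > len(extra):
                raise ConfigError(
                    f"chapter {ch.id} has only {len(space) + len(extra)} codes available"
                )
            space = space + _sample_distinct(rng, extra, need)
        for c in _sample_distinct(rng, space, config.codes_per_chapter):
            code = IcdCode(c)
            codes.append(code)
            chapter_of_code[code] = ch.id
    codes.sort()

    genes = [GeneSymbol(f"G{i:05d}") for i in range(config.n_genes)]
    shuffled = list(genes)
    rng.shuffle(shuffled)
    pool_size = max(1, config.n_genes // config.n_chapters)
    chapter_pools = {
        ch.id: shuffled[i * pool_size : (i + 1) * pool_size] or shuffled[:pool_size]
        for i, ch in enumerate(chapters)
    }
    other_chapters = {
        ch.id: [c.id for c in chapters if c.id != ch.id] or [ch.id] for ch in chapters
    }

    lo_g, hi_g = config.genes_per_disease
    profiles: dict[IcdCode, set[GeneSymbol]] = {}
    for code in codes:
        ch_id = chapter_of_code[code]
        k = int(rng.integers(lo_g, hi_g + 1))
        prof: set[GeneSymbol] = set()
        for _ in range(k):
            u = rng.random()
            if u < config.p_within:
                pool = chapter_pools[ch_id]
            elif u < config.p_within + config.p_between:
                others = other_chapters[ch_id]
                pool = chapter_pools[others[int(rng.integers(len(others)))]]
            else:
                pool = genes
            prof.add(pool[int(rng.integers(len(pool)))])
        profiles[code] = prof

    # Plant subset pairs on disjoint codes: profile(Y) := profile(X) + extras.
    planted_codes = _sample_distinct(rng, codes, 2 * config.n_subset_pairs)
    subset_pairs: list[tuple[IcdCode, IcdCode]] = []
    for i in range(config.n_subset_pairs):
        x, y = planted_codes[2 * i], planted_codes[2 * i + 1]
        if not profiles[x]:
            profiles[x].add(genes[int(rng.integers(len(genes)))])
        extras: set[GeneSymbol] = set()
        n_extra = 1 + int(rng.integers(0, 3))
        while len(extras) < n_extra:
            g = genes[int(rng.integers(len(genes)))]
            if g not in profiles[x]:
                extras.add(g)
        profiles[y] = set(profiles[x]) | extras
        subset_pairs.append((x, y))

    # Pathway universe mixing the three KEGG identifier classes.
    pathways: list[PathwayId] = []
    for i in range(config.n_pathways):
        if i % 5 < 3:
            pathways.append(PathwayId(f"ko{10000 + i}"))
        elif i % 5 == 3:
            pathways.append(PathwayId(f"M{10000 + i}"))
        else:
            pathways.append(PathwayId(f"H{10000 + i}"))

    lo_p, hi_p = config.pathways_per_gene
    gene_pathways: dict[GeneSymbol, set[PathwayId]] = {}
    for g in genes:
        m = int(rng.integers(lo_p, hi_p + 1))
        gene_pathways[g] = set(_sample_distinct(rng, pathways, m))

    dg_approved = sorted(
        DiseaseGeneAssociation(code, g) for code, prof in profiles.items() for g in prof
    )
    gp_pool = sorted(
        GenePathwayAssociation(g, p) for g, ps in gene_pathways.items() for p in ps
    )

    # Disease pathway profiles (via the tripartite join) drive enrichment planting.
    triples = build_tripartite(dg_approved, gp_pool)
    d_path = {pr.entity: pr.elements for pr in disease_pathway_profiles(triples)}
    eligible = sorted(c for c, ps in d_path.items() if len(ps) >= 2)
    if config.n_planted_enriched > len(eligible):
        raise ConfigError(
            f"only {len(eligible)} diseases have >= 2 pathways; cannot plant "
            f"{config.n_planted_enriched} enriched pairs"
        )
    target_codes = _sample_distinct(rng, eligible, config.n_planted_enriched)

    enriched_pairs: list[tuple[GeneSymbol, IcdCode]] = []
    candidate_pathways: dict[GeneSymbol, set[PathwayId]] = {}
    for i, code in enumerate(target_codes):
        gene = GeneSymbol(f"CAND{i:04d}")
        prof = sorted(d_path[code])
        m = max(1, round(config.planted_overlap * len(prof)))
        candidate_pathways[gene] = set(_sample_distinct(rng, prof, m))
        enriched_pairs.append((gene, code))
    for i in range(config.n_background_candidates):
        gene = GeneSymbol(f"BG{i:05d}")
        m = int(rng.integers(lo_p, hi_p + 1))
        candidate_pathways[gene] = set(_sample_distinct(rng, pathways, m))

    # Alias a fraction of the genes appearing in the disease-gene map; those
    # rows are written under the raw (previous/alias) symbol.
    appearing = sorted({a.gene for a in dg_approved})
    n_alias = min(round(config.alias_rate * config.n_genes), len(appearing))
    aliased = _sample_distinct(rng, appearing, n_alias)
    raw_of: dict[GeneSymbol, GeneSymbol] = {}
    alias_tier: dict[GeneSymbol, str] = {}
    for g in aliased:
        raw = GeneSymbol(f"{g}-OLD")
        raw_of[g] = raw
        alias_tier[g] = "previous" if rng.random() < 0.5 else "alias"

    hgnc_records: list[HgncRecord] = []
    for g in sorted(set(genes) | set(candidate_pathways)):
        prev: frozenset = frozenset()
        alias: frozenset = frozenset()
        if g in raw_of:
            if alias_tier[g] == "previous":
                prev = frozenset({raw_of[g]})
            else:
                alias = frozenset({raw_of[g]})
        hgnc_records.append(
            HgncRecord(approved=g, previous=prev, aliases=alias, status="approved")
        )

    dg_raw = sorted(
        DiseaseGeneAssociation(a.code, raw_of.get(a.gene, a.gene)) for a in dg_approved
    )
    gp_all = sorted(
        gp_pool
        + [
            GenePathwayAssociation(g, p)
            for g, ps in candidate_pathways.items()
            for p in ps
        ]
    )

    truth = GroundTruth(
        subset_pairs=sorted(subset_pairs),
        enriched_pairs=sorted(enriched_pairs),
        alias_map={raw: g for g, raw in sorted(raw_of.items())},
    )
    return SyntheticStudy(
        config=config,
        chapters=chapters,
        hgnc=hgnc_records,
        disease_gene=dg_raw,
        gene_pathway=gp_all,
        truth=truth,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """How well an enrichment run recovered the planted gene-disease pairs."""

    n_planted: int
    n_evaluated: int
    recall: float
    median_planted_rank: float
    background_rank_5th_percentile: float
    planted_outrank_background: bool


def measure_against_truth(
    result,
    truth: GroundTruth,
    alpha: float | None = None,
) -> RecoveryReport:
    """Recall of planted pairs at ``alpha`` and rank comparison vs background.

    Ranks are taken over the full evaluated list (rank 1 = most enriched);
    the planted pairs "outrank" the background when their median rank is
    at or better than the 5th numeric percentile of background ranks, i.e.
    better than 95 % of non-planted pairs.  A planted pair absent from a
    non-empty evaluated list means predictions and truth come from
    different studies and raises :class:`IntegrityError`.
    """
    alpha = result.alpha if alpha is None else alpha
    planted = set(truth.enriched_pairs)
    evaluated: Sequence[Prediction] = result.evaluated
    if not planted:
        return RecoveryReport(0, len(evaluated), 1.0, float("nan"), float("nan"), True)
    if not evaluated:
        return RecoveryReport(
            len(planted), 0, 0.0, float("nan"), float("nan"), False
        )
    eval_pairs = {(p.gene, p.code): p for p in evaluated}
    missing = planted - set(eval_pairs)
    if missing:
        raise IntegrityError(
            f"{len(missing)} planted pair(s) absent from the evaluated list "
            f"(e.g. {sorted(missing)[:3]}); predictions do not match this study"
        )
    planted_ranks = [eval_pairs[pair].rank for pair in planted]
    background_ranks = [
        p.rank for p in evaluated if (p.gene, p.code) not in planted
    ]
    kept = sum(1 for pair in planted if eval_pairs[pair].p_value <= alpha)
    recall = kept / len(planted)
    med = float(np.median(planted_ranks))
    p5 = (
        float(np.percentile(background_ranks, 5)) if background_ranks else float("inf")
    )
    return RecoveryReport(
        n_planted=len(planted),
        n_evaluated=len(evaluated),
        recall=recall,
        median_planted_rank=med,
        background_rank_5th_percentile=p5,
        planted_outrank_background=med <= p5,
    )
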