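"""Synthetic data generators for the full pipeline.

Every downstream stage — fragment reassignment, batch adjustment, adaptive
filtering, differential expression, family enrichment, proximal-gene pathway
analysis and correlation — is testable against known ground truth produced
here.  All generators are pure functions of their arguments including the
seed.

The simulated world is deliberately small: up to five 1 Mb chromosomes,
dozens-to-hundreds of retroviral loci with family labels drawn from a skewed
frequency distribution, single-end fragments with a tunable fraction of
ambiguous (multi-mapped) alignments, and negative-binomial count matrices
with planted log2 fold changes and multiplicative batch effects across
case/control samples from several batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneAnnotation, LocusAnnotation
from .matrix import CountMatrix, SampleDesign, write_gmt

CHROM_LENGTH = 1_000_000
MAX_CHROMS = 5
READ_LENGTH = 75
TRUE_SCORE = 100  # AS of the locus-of-origin alignment


@dataclass
class SimTruth:
    """Ground truth attached to a simulation run."""

    seed: int
    true_proportions: dict[str, float] = field(default_factory=dict)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    batch_factor: dict[tuple[str, str], float] = field(default_factory=dict)
    true_de_set: set[str] = field(default_factory=set)
    fragment_origin: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_proportions:
            total = sum(self.true_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"true_proportions must sum to 1 (got {total})")
        for f in self.true_de_set:
            if self.true_log2fc.get(f, 0.0) == 0.0:
                raise ValueError(f"DE feature {f} has zero log2fc")


class CapacityError(ValueError):
    """Requested more annotation than fits on the toy chromosomes."""


def _band_name(chrom: str, start: int) -> str:
    """Cytogenetic-style band label derived deterministically from position."""
    num = chrom.removeprefix("chr")
    arm = "p" if start < CHROM_LENGTH // 2 else "q"
    major = 11 + (start // 37_000) % 26
    sub = (start // 7_001) % 4
    band = f"{num}{arm}{major}"
    if sub:
        band += f".{sub}"
    return band


def make_toy_annotation(
    n_loci: int,
    n_genes: int,
    n_chromosomes: int = 3,
    family_weights: dict[str, float] | None = None,
    frac_intragenic: float = 0.3,
    seed: int = 0,
) -> tuple[list[LocusAnnotation], list[GeneAnnotation]]:
    """Place genes and retroviral loci on a toy genome.

    Loci receive family labels sampled proportionally to ``family_weights``
    and names following the FAMILY_band+letter convention (e.g.
    ``MER101_6q27d``; the copy letter appears only when several loci of one
    family share a band).  Approximately ``frac_intragenic`` of the loci are
    placed inside a gene body; the rest land in intergenic space.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0 <= frac_intragenic <= 1:
        raise ValueError("frac_intragenic must be in [0, 1]")
    if not 1 <= n_chromosomes <= MAX_CHROMS:
        raise ValueError(f"n_chromosomes must be in [1, {MAX_CHROMS}]")
    family_weights = family_weights or {"HML2": 3.0, "MER101": 2.0, "HERVL": 1.0}
    if not family_weights:
        raise ValueError("family_weights must be nonempty")

    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]

    # genes: laid sequentially per chromosome with random gaps
    genes: list[GeneAnnotation] = []
    cursor = {c: 1000 for c in chroms}
    for i in range(n_genes):
        chrom = chroms[i % n_chromosomes]
        gap = int(rng.integers(2_000, 20_000))
        length = int(rng.integers(3_000, 12_000))
        start = cursor[chrom] + gap
        end = start + length
        if end > CHROM_LENGTH - 1000:
            raise CapacityError(
                f"cannot place {n_genes} genes on {n_chromosomes} toy chromosomes"
            )
        cursor[chrom] = end
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"G{i + 1:04d}", chrom, start, end, strand))

    families = sorted(family_weights)
    weights = np.array([family_weights[f] for f in families], dtype=float)
    weights /= weights.sum()
    fam_draw = rng.choice(len(families), size=n_loci, replace=True, p=weights)
    intragenic = rng.random(n_loci) < frac_intragenic

    gene_ivs = {c: [(g.start, g.end) for g in genes if g.chrom == c] for c in chroms}
    placed: list[tuple[str, str, int, int, str]] = []  # family, chrom, start, end, strand
    for i in range(n_loci):
        family = families[fam_draw[i]]
        length = int(rng.integers(500, 3_000))
        if intragenic[i] and genes:
            g = genes[int(rng.integers(len(genes)))]
            length = min(length, g.end - g.start - 10)
            start = int(rng.integers(g.start, g.end - length))
            chrom = g.chrom
        else:
            chrom, start = None, None
            for _ in range(1000):
                c = chroms[int(rng.integers(n_chromosomes))]
                s = int(rng.integers(0, CHROM_LENGTH - length))
                if not any(s < e and b < s + length for b, e in gene_ivs[c]):
                    chrom, start = c, s
                    break
            if chrom is None:
                raise CapacityError("no intergenic space left for loci")
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append((family, chrom, start, start + length, strand))

    # name loci: FAMILY_band, with copy letters when a family+band collides
    keys = [(fam, _band_name(chrom, start)) for fam, chrom, start, _e, _s in placed]
    from collections import Counter

    multiplicity = Counter(keys)
    letter_idx: dict[tuple[str, str], int] = {}
    loci: list[LocusAnnotation] = []
    for (family, chrom, start, end, strand), key in zip(placed, keys):
        name = f"{family}_{key[1]}"
        if multiplicity[key] > 1:
            k = letter_idx.get(key, 0)
            letter_idx[key] = k + 1
            name += chr(ord("a") + k)
        loci.append(LocusAnnotation(name, chrom, start, end, strand, family))
    return loci, genes


def simulate_fragments(
    loci: list[LocusAnnotation],
    true_proportions: dict[str, float],
    n_fragments: int,
    ambiguity_rate: float = 0.3,
    score_gap: float = 5.0,
    seed: int = 0,
    sam_path: str | Path = "fragments.sam",
    read_length: int = READ_LENGTH,
) -> SimTruth:
    """Write multi-mapped single-end alignments with known loci of origin.

    Each fragment originates from one locus drawn from ``true_proportions``.
    With probability ``ambiguity_rate`` it additionally aligns to 1-3 decoy
    loci whose AS score is lower than the true alignment's by a
    Poisson(``score_gap``) draw — ``score_gap=0`` yields exact score ties.
    Output is byte-identical for a fixed seed.
    """
    if not 0 <= ambiguity_rate <= 1:
        raise ValueError("ambiguity_rate must be in [0, 1]")
    if set(true_proportions) != {l.locus_id for l in loci}:
        raise ValueError("true_proportions must cover exactly the given loci")
    if abs(sum(true_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("true_proportions must sum to 1")
    if len(loci) < 2 and ambiguity_rate > 0:
        raise ValueError("ambiguity requires at least 2 loci to draw decoys from")

    rng = np.random.default_rng(seed)
    loci = sorted(loci, key=lambda l: l.locus_id)
    probs = np.array([true_proportions[l.locus_id] for l in loci])
    chroms = sorted({l.chrom for l in loci})

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": c, "LN": CHROM_LENGTH} for c in chroms],
        }
    )
    truth = SimTruth(seed=seed)
    origins = rng.choice(len(loci), size=n_fragments, p=probs)
    width = max(6, len(str(max(n_fragments - 1, 1))))

    def _aln(name: str, locus: LocusAnnotation, score: int, secondary: bool) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = 256 if secondary else 0
        a.reference_id = chroms.index(locus.chrom)
        span = min(read_length, locus.end - locus.start)
        hi = locus.end - span
        a.reference_start = int(rng.integers(locus.start, hi + 1))
        a.mapping_quality = 3 if secondary else 30
        a.cigarstring = f"{span}M"
        a.set_tag("AS", int(score))
        return a

    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for i in range(n_fragments):
            name = f"frag{i:0{width}d}"
            true_locus = loci[origins[i]]
            truth.fragment_origin[name] = true_locus.locus_id
            out.write(_aln(name, true_locus, TRUE_SCORE, secondary=False))
            if rng.random() < ambiguity_rate:
                n_decoys = min(int(rng.integers(1, 4)), len(loci) - 1)
                others = [j for j in range(len(loci)) if j != origins[i]]
                decoys = rng.choice(others, size=n_decoys, replace=False)
                for j in decoys:
                    gap = int(rng.poisson(score_gap))
                    out.write(_aln(name, loci[j], TRUE_SCORE - gap, secondary=True))

    truth.true_proportions = {l.locus_id: float(p) for l, p in zip(loci, probs)}
    return truth


def make_design(
    n_case: int = 5,
    n_control: int = 5,
    batches: tuple[str, ...] = ("b1",),
    library_size_factors: dict[str, float] | None = None,
) -> list[SampleDesign]:
    """Balanced case/control design with samples cycled across batches."""
    design = []
    for cond, n in (("case", n_case), ("control", n_control)):
        for i in range(n):
            sid = f"{cond}{i + 1}"
            batch = batches[i % len(batches)]
            lsf = (library_size_factors or {}).get(sid, 1.0)
            design.append(SampleDesign(sid, cond, batch, lsf))
    return design


def simulate_counts(
    design: list[SampleDesign],
    n_features: int,
    frac_de: float = 0.1,
    lfc_magnitude: float = 1.0,
    dispersion: float = 0.1,
    batch_log2_shift: float = 0.0,
    seed: int = 0,
    feature_prefix: str = "F",
    baseline_range: tuple[float, float] = (20.0, 500.0),
) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial counts with planted fold changes and batch effects.

    Feature i in sample j has mean
    ``baseline_i * 2^(lfc_i * [condition_j == case]) * 2^(s_i * shift * b_j) * lsf_j``
    where ``b_j`` is the 0-based index of sample j's batch and ``s_i`` is a
    per-feature random sign.  The sign makes the batch effect
    feature-heterogeneous — each feature is shifted by exactly
    ``2^batch_log2_shift`` up or down per batch step — so that the effect
    is orthogonal to library depth instead of masquerading as a size
    factor.  Counts are NB(mean, dispersion) with Var = mu + disp * mu^2.
    """
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    conds = {s.condition for s in design}
    for c in conds:
        if sum(s.condition == c for s in design) < 2:
            raise ValueError(f"need >= 2 samples in condition {c}")

    rng = np.random.default_rng(seed)
    features = [f"{feature_prefix}{i + 1:05d}" for i in range(n_features)]
    lo, hi = baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_features))

    n_de = int(round(frac_de * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    lfc = np.zeros(n_features)
    lfc[de_idx] = lfc_magnitude * rng.choice([-1.0, 1.0], size=n_de)

    batch_levels = sorted({s.batch for s in design})
    batch_index = {b: i for i, b in enumerate(batch_levels)}
    batch_sign = rng.choice([-1.0, 1.0], size=n_features)

    is_case = np.array([s.condition == "case" for s in design], dtype=float)
    b_j = np.array([batch_index[s.batch] for s in design], dtype=float)
    lsf = np.array([s.library_size_factor for s in design])

    mu = (
        baseline[:, None]
        * 2.0 ** (lfc[:, None] * is_case[None, :])
        * 2.0 ** (batch_sign[:, None] * batch_log2_shift * b_j[None, :])
        * lsf[None, :]
    )
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    cm = CountMatrix(
        pd.DataFrame(counts, index=features, columns=[s.sample_id for s in design]),
        list(design),
    )
    truth = SimTruth(
        seed=seed,
        true_log2fc={f: float(v) for f, v in zip(features, lfc)},
        batch_factor={
            (b, f): float(2.0 ** (batch_sign[i] * batch_log2_shift * batch_index[b]))
            for b in batch_levels
            for i, f in enumerate(features)
        },
        true_de_set={features[i] for i in de_idx},
    )
    return cm, truth


def make_pathway_db(
    genes: list[GeneAnnotation],
    n_pathways: int,
    size_range: tuple[int, int] = (5, 20),
    seed: int = 0,
    path: str | Path | None = None,
) -> dict[str, set[str]]:
    """Sample named gene sets over the toy universe; optionally write GMT."""
    lo, hi = size_range
    if lo > hi:
        raise ValueError(f"size_range inverted: {size_range}")
    gene_ids = sorted(g.gene_id for g in genes)
    if hi > len(gene_ids):
        raise ValueError("max pathway size exceeds number of genes")
    rng = np.random.default_rng(seed)
    pathways = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        pathways[f"PW{i + 1:03d}"] = set(members.tolist())
    if path is not None:
        write_gmt(pathways, path)
    return pathways


def toy_signature(genes: list[GeneAnnotation], n: int = 10, seed: int = 0) -> list[str]:
    """A toy interferon-signature gene list sampled from the universe."""
    rng = np.random.default_rng(seed)
    ids = sorted(g.gene_id for g in genes)
    n = min(n, len(ids))
    return sorted(rng.choice(ids, size=n, replace=False).tolist())


def write_truth_tables(truth: SimTruth, out_dir: str | Path) -> None:
    """TSV dumps of the ground truth for inspection and reporting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth.fragment_origin:
        pd.Series(truth.fragment_origin, name="true_locus").rename_axis(
            "fragment"
        ).to_csv(out / "fragment_truth.tsv", sep="\t")
    if truth.true_proportions:
        pd.Series(truth.true_proportions, name="proportion").rename_axis(
            "locus_id"
        ).to_csv(out / "proportions_truth.tsv", sep="\t")
    if truth.true_log2fc:
        df = pd.DataFrame(
            {
                "true_log2fc": pd.Series(truth.true_log2fc),
                "is_de": pd.Series(
                    {f: f in truth.true_de_set for f in truth.true_log2fc}
                ),
            }
        ).rename_axis("feature_id")
        df.to_csv(out / "de_truth.tsv", sep="\t")
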