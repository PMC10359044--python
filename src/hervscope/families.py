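"""Locus-name parsing, family over-representation and chromosomal
distribution of differentially expressed retroviral loci.

Locus names follow the FAMILY_band+letter convention, e.g. ``MER101_6q27d``:
family MER101, cytogenetic band 6q27, copy ``d`` of that band.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .annotation import LocusAnnotation
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

_BAND_RE = re.compile(r"^([0-9XYM]+[pq][0-9.]*?)([a-z]?)$")


def parse_locus_name(locus_id: str) -> tuple[str, str, str]:
    """Split a locus id into (family, cytoband, copy_suffix).

    The family is everything before the final underscore; the remainder is
    a chromosome+band string with an optional trailing copy letter.
    Names without an underscore yield (whole string, "", "") with a warning.
    """
    if "_" not in locus_id:
        logger.warning("locus id %r has no underscore; treating as bare family", locus_id)
        return locus_id, "", ""
    family, _, rest = locus_id.rpartition("_")
    m = _BAND_RE.match(rest)
    if m is None:
        logger.warning("locus id %r has unparseable band %r", locus_id, rest)
        return family, rest, ""
    return family, m.group(1), m.group(2)


@dataclass
class FamilyEnrichment:
    family: str
    n_db: int
    n_de: int
    freq_db: float
    freq_de: float
    ratio: float


def _family_of(locus: LocusAnnotation) -> str:
    if locus.family:
        parsed = parse_locus_name(locus.locus_id)[0]
        if parsed != locus.family and "_" in locus.locus_id:
            logger.debug(
                "family label %r disagrees with name-derived %r for %s",
                locus.family, parsed, locus.locus_id,
            )
        return locus.family
    return parse_locus_name(locus.locus_id)[0]


def family_enrichment(
    de_loci: set[str],
    db_loci: list[LocusAnnotation],
    with_pvalues: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Per-family frequency ratio of DE loci versus the full database.

    ratio = (n_de / total_de) / (n_db / total_db); families absent from the
    DE set get ratio 0.  Under proportional sampling every ratio is 1, so
    the expected ratio is 1.  Optionally attaches a hypergeometric
    over-representation p per family with BH adjustment.
    """
    ids = {l.locus_id for l in db_loci}
    unknown = sorted(de_loci - ids)
    if unknown:
        raise ValueError(f"DE loci absent from the database: {unknown}")

    fam_of = {l.locus_id: _family_of(l) for l in db_loci}
    total_db = len(db_loci)
    total_de = len(de_loci)
    rows = []
    for fam in sorted({fam_of[i] for i in ids}):
        n_db = sum(1 for i in ids if fam_of[i] == fam)
        n_de = sum(1 for i in de_loci if fam_of[i] == fam)
        freq_db = n_db / total_db
        freq_de = n_de / total_de if total_de else 0.0
        rows.append(
            {
                "family": fam,
                "n_db": n_db,
                "n_de": n_de,
                "freq_db": freq_db,
                "freq_de": freq_de,
                "ratio": freq_de / freq_db if n_db else float("nan"),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["ratio", "family"], ascending=[False, True]
    ).reset_index(drop=True)
    if with_pvalues and len(df):
        # P(X >= n_de) drawing total_de loci without replacement
        df["p"] = [
            float(hypergeom.sf(r.n_de - 1, total_db, r.n_db, total_de))
            for r in df.itertuples()
        ]
        df["q"] = bh_adjust(df["p"].to_numpy())
    expected_ratio = 1.0
    return df, expected_ratio


def chromosome_distribution(
    de_loci: set[str], db: list[LocusAnnotation]
) -> pd.DataFrame:
    """Counts of DE and database loci per chromosome (circos-ready)."""
    ids = {l.locus_id for l in db}
    unknown = sorted(de_loci - ids)
    if unknown:
        raise ValueError(f"DE loci absent from the database: {unknown}")
    chrom_of = {l.locus_id: l.chrom for l in db}
    chroms = sorted({l.chrom for l in db})
    rows = [
        {
            "chrom": c,
            "n_de": sum(1 for i in de_loci if chrom_of[i] == c),
            "n_db": sum(1 for l in db if l.chrom == c),
        }
        for c in chroms
    ]
    return pd.DataFrame(rows)
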