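"""C-to-U RNA editing quantification from per-site base counts.

Plant mitochondrial transcripts are edited C->U; on a minus-strand gene the
edit is observed as G->A in plus-strand pileup counts. Editing rate at a site
is alt/(ref+alt) on the coding strand — sequencing errors to the other two
bases are excluded from the denominator. A gDNA amplicon serves as negative
control: an apparent edit present in gDNA is a genomic variant, not editing.

Coordinates are 1-based inclusive. For a minus-strand CDS whose start codon's
first base sits at plus-strand position ``start_anchor``,

    cds_pos = start_anchor - contig_pos + 1,

so contig_pos + cds_pos is constant (anchor + 1) across the gene; for a
plus-strand CDS, cds_pos = contig_pos - start_anchor + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .orfs import translate

PILEUP_COLUMNS = [
    "contig", "pos", "ref_base", "count_A", "count_C", "count_G", "count_T",
    "sample_id",
]


@dataclass
class CdsCoordinateMap:
    contig_id: str
    strand: str
    start_anchor: int  # contig position of the first base of the start codon
    cds_length: Optional[int] = None  # nt, including the stop codon if desired

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.start_anchor < 1:
            raise ValueError("start_anchor must be a positive 1-based position")


def cds_position(contig_pos: int, cmap: CdsCoordinateMap) -> int:
    if cmap.strand == "-":
        cds = cmap.start_anchor - contig_pos + 1
    else:
        cds = contig_pos - cmap.start_anchor + 1
    if cds < 1 or (cmap.cds_length is not None and cds > cmap.cds_length):
        raise ValueError(
            f"contig position {contig_pos} outside the CDS span of "
            f"{cmap.contig_id} (cds_pos={cds})"
        )
    return cds


def contig_position(cds_pos: int, cmap: CdsCoordinateMap) -> int:
    if cds_pos < 1 or (cmap.cds_length is not None and cds_pos > cmap.cds_length):
        raise ValueError(f"CDS position {cds_pos} outside the CDS span")
    if cmap.strand == "-":
        return cmap.start_anchor - cds_pos + 1
    return cmap.start_anchor + cds_pos - 1


def infer_start_anchor(
    paired_coordinates: Sequence[tuple[int, int]],
    contig_id: str = "",
    cds_length: Optional[int] = None,
) -> CdsCoordinateMap:
    """Solve strand and start-codon anchor from (contig_pos, cds_pos) pairs.

    On the minus strand contig_pos + cds_pos is constant (= anchor + 1); on
    the plus strand contig_pos - cds_pos is constant (= anchor - 1). At least
    two distinct consistent pairs are required; inconsistent pairs raise.
    """
    pairs = list(dict.fromkeys(paired_coordinates))
    if len(pairs) < 2:
        raise ValueError("need at least two distinct (contig_pos, cds_pos) pairs")
    sums = {c + p for c, p in pairs}
    diffs = {c - p for c, p in pairs}
    if len(sums) == 1:
        return CdsCoordinateMap(contig_id, "-", sums.pop() - 1, cds_length)
    if len(diffs) == 1:
        return CdsCoordinateMap(contig_id, "+", diffs.pop() + 1, cds_length)
    raise ValueError(f"coordinate pairs are inconsistent: {pairs}")


def validate_pileup(df: pd.DataFrame) -> pd.DataFrame:
    for col in PILEUP_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"pileup table missing required column {col!r}")
    return df


def base_counts(
    pileup: pd.DataFrame,
    contig: str,
    start: int,
    end: int,
) -> pd.DataFrame:
    """Per-site A/C/G/T counts per sample over [start, end] on the plus strand.

    Zero-coverage positions inside the region are reported with zero counts,
    not omitted. The region is given in plus-strand coordinates (start <= end).
    """
    validate_pileup(pileup)
    if start > end:
        start, end = end, start
    sel = pileup[(pileup["contig"] == contig) & pileup["pos"].between(start, end)]
    samples = sorted(sel["sample_id"].unique()) or []
    full = pd.MultiIndex.from_product(
        [samples, range(start, end + 1)], names=["sample_id", "pos"]
    )
    out = (
        sel.set_index(["sample_id", "pos"])
        [["ref_base", "count_A", "count_C", "count_G", "count_T"]]
        .reindex(full)
    )
    ref = sel.drop_duplicates("pos").set_index("pos")["ref_base"]
    out["ref_base"] = out.index.get_level_values("pos").map(ref)
    for c in ("count_A", "count_C", "count_G", "count_T"):
        out[c] = out[c].fillna(0).astype(int)
    out["contig"] = contig
    return out.reset_index()


def editing_rate(
    count_A: int, count_C: int, count_G: int, count_T: int, strand: str
) -> Optional[float]:
    """C->U editing rate on the coding strand from plus-strand base counts.

    Plus-strand gene: rate = T/(C+T); minus-strand gene: the coding C appears
    as plus-strand G and the edited U as plus-strand A, so rate = A/(G+A).
    Returns None when ref+alt coverage is zero (undefined, flagged upstream).
    """
    if strand == "+":
        ref, alt = count_C, count_T
    elif strand == "-":
        ref, alt = count_G, count_A
    else:
        raise ValueError("strand must be '+' or '-'")
    if ref + alt == 0:
        return None
    return alt / (ref + alt)


@dataclass
class EditingSite:
    contig_id: str
    contig_pos: int
    cds_pos: int
    codon_index: int
    codon_offset: int
    ref_base: str           # coding strand (always C for C->U sites)
    alt_base: str           # coding strand (T, i.e. U in the transcript)
    aa_ref: str
    aa_alt: str
    synonymous: bool
    label: str              # e.g. L20F, F10F
    rates: dict[str, dict[str, float]] = field(default_factory=dict)
    gdna_rate: Optional[float] = None
    controlled: bool = True
    coverage: int = 0


def codon_effect(
    cds_sequence: str, cds_pos: int, alt_base: str
) -> tuple[int, int, str, str, bool, str]:
    """Effect of substituting ``alt_base`` at ``cds_pos`` of a CDS.

    Returns (codon_index, codon_offset, aa_ref, aa_alt, synonymous, label)
    with label of the form ``L20F`` (or ``F10F`` when synonymous).
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    if not 1 <= cds_pos <= len(cds):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {len(cds)}")
    codon_index = math.ceil(cds_pos / 3)
    codon_offset = cds_pos - 3 * (codon_index - 1)
    codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    alt_codon = (
        codon[: codon_offset - 1] + alt_base.upper() + codon[codon_offset:]
    )
    aa_ref = translate(codon)
    aa_alt = translate(alt_codon)
    synonymous = aa_ref == aa_alt
    label = f"{aa_ref}{codon_index}{aa_alt}"
    return codon_index, codon_offset, aa_ref, aa_alt, synonymous, label


@dataclass
class EditingThresholds:
    min_rate: float = 0.05
    min_coverage: int = 100
    control_max: float = 0.01


def detect_editing_sites(
    cdna_counts: pd.DataFrame,
    gdna_counts: Optional[pd.DataFrame],
    cmap: CdsCoordinateMap,
    cds_sequence: str,
    sample_groups: Optional[dict[str, str]] = None,
    thresholds: EditingThresholds = EditingThresholds(),
) -> list[EditingSite]:
    """Detect C->U editing sites within a gene from cDNA base counts.

    A site is called where the coding-strand base is C, the pooled cDNA
    editing rate is >= min_rate at pooled ref+alt coverage >= min_coverage,
    and the gDNA control rate is <= control_max. Without a gDNA table sites
    are still reported but flagged uncontrolled. ``cdna_counts``/``gdna_counts``
    are pileup tables (see PILEUP_COLUMNS); ``sample_groups`` maps sample_id
    to a replicate-group name for the per-group rate breakdown.
    """
    validate_pileup(cdna_counts)
    if gdna_counts is not None:
        validate_pileup(gdna_counts)
    cds = cds_sequence.upper()
    sites: list[EditingSite] = []
    n_cds = cmap.cds_length or len(cds)
    for cds_pos in range(1, min(len(cds), n_cds) + 1):
        if cds[cds_pos - 1] != "C":
            continue
        cpos = contig_position(cds_pos, cmap)
        rows = cdna_counts[
            (cdna_counts["contig"] == cmap.contig_id) & (cdna_counts["pos"] == cpos)
        ]
        if rows.empty:
            continue
        pooled = rows[["count_A", "count_C", "count_G", "count_T"]].sum()
        rate = editing_rate(
            pooled["count_A"], pooled["count_C"], pooled["count_G"],
            pooled["count_T"], cmap.strand,
        )
        if cmap.strand == "+":
            cov = int(pooled["count_C"] + pooled["count_T"])
        else:
            cov = int(pooled["count_G"] + pooled["count_A"])
        if rate is None or cov < thresholds.min_coverage or rate < thresholds.min_rate:
            continue
        gdna_rate = None
        controlled = gdna_counts is not None
        if controlled:
            grows = gdna_counts[
                (gdna_counts["contig"] == cmap.contig_id)
                & (gdna_counts["pos"] == cpos)
            ]
            if grows.empty:
                controlled = False
            else:
                gp = grows[["count_A", "count_C", "count_G", "count_T"]].sum()
                gdna_rate = editing_rate(
                    gp["count_A"], gp["count_C"], gp["count_G"], gp["count_T"],
                    cmap.strand,
                )
                if gdna_rate is not None and gdna_rate > thresholds.control_max:
                    continue  # genomic variant, not editing
        ci, off, aa_ref, aa_alt, syn, label = codon_effect(cds, cds_pos, "T")
        per_group: dict[str, dict[str, float]] = {}
        for _, r in rows.iterrows():
            sample = r["sample_id"]
            group = (sample_groups or {}).get(sample, "all")
            sr = editing_rate(
                r["count_A"], r["count_C"], r["count_G"], r["count_T"], cmap.strand
            )
            if sr is not None:
                per_group.setdefault(group, {})[sample] = sr
        sites.append(
            EditingSite(
                contig_id=cmap.contig_id,
                contig_pos=cpos,
                cds_pos=cds_pos,
                codon_index=ci,
                codon_offset=off,
                ref_base="C",
                alt_base="T",
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                synonymous=syn,
                label=label,
                rates=per_group,
                gdna_rate=gdna_rate,
                controlled=controlled,
                coverage=cov,
            )
        )
    sites.sort(key=lambda s: s.cds_pos)
    return sites


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_groups(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    group_a: str = "A",
    group_b: str = "B",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test on per-replicate editing rates.

    Welch's unequal-variance variant by default (robust at n = 3); pass
    ``equal_var=True`` for Student's variant. Two zero-variance groups with
    equal means give t = 0, p = 1.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
        if math.isnan(p):
            t, p = 0.0, 1.0
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(len(x)))
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=sem(a),
        sem_b=sem(b),
        t_statistic=t,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )


def site_table(
    sites: Iterable[EditingSite],
    comparisons: Optional[dict[int, GroupComparison]] = None,
) -> pd.DataFrame:
    """Flatten EditingSite records (plus optional per-site group tests) to TSV form."""
    rows = []
    for s in sites:
        row = {
            "contig": s.contig_id,
            "contig_pos": s.contig_pos,
            "cds_pos": s.cds_pos,
            "codon_index": s.codon_index,
            "codon_offset": s.codon_offset,
            "label": s.label,
            "synonymous": s.synonymous,
            "coverage": s.coverage,
            "gdna_rate": s.gdna_rate,
            "controlled": s.controlled,
        }
        for group, samples in sorted(s.rates.items()):
            for sample, rate in sorted(samples.items()):
                row[f"rate_{group}_{sample}"] = rate
        if comparisons and s.cds_pos in comparisons:
            c = comparisons[s.cds_pos]
            row.update(
                t=c.t_statistic, p=c.p_value, significant=c.significant,
                mean_a=c.mean_a, mean_b=c.mean_b,
            )
        rows.append(row)
    return pd.DataFrame(rows)
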