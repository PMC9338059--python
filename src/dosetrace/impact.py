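"""Result assembly: proteome-impact table, phospho-response table,
per-protein heterogeneity, and hypergeometric gene-set enrichment.

The proteome-impact table pairs each protein's replicate-mean average slope
at 37 °C (constitutive abundance) with the one at 52 °C (thermal stability
of the soluble fraction); a protein is a hit when the slope magnitude on
either axis exceeds the hit threshold (0.5 by default). Enrichment of a hit
list against the background of all identified proteins uses the upper-tail
hypergeometric probability with a raw p < 0.05 significance flag; a
Benjamini-Hochberg FDR column is emitted alongside but does not drive the
flag.
"""

from __future__ import annotations

import math
from collections import defaultdict
from fractions import Fraction
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .classify import ResponseCategory, SiteCall
from .smoothing import FittedCurve


@dataclass(frozen=True)
class EntityCurve:
    """A fitted curve tagged with the entity/condition it belongs to."""

    entity_id: str
    gene: str
    temperature: int
    replicate_id: int
    curve: FittedCurve


@dataclass(frozen=True)
class ImpactRecord:
    """One protein's 37 °C and 52 °C average slopes with its hit flag.

    A missing temperature axis is carried as NaN and the hit decision is
    made on the present axis alone.
    """

    protein_id: str
    gene: str
    slope_37: float
    slope_52: float
    is_kinase: bool
    is_hit: bool


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_k: int
    set_size_K: int
    hits_n: int
    background_N: int
    p_value: float
    bh_fdr: float
    significant: bool


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Which non-NR categories co-occur among each protein's sites."""

    per_protein: Mapping[str, frozenset[ResponseCategory]]
    combination_counts: Mapping[frozenset[ResponseCategory], int]


def proteome_impact(
    entity_curves: Iterable[EntityCurve],
    hit_threshold: float = 0.5,
    *,
    kinases: Iterable[str] = (),
    two_sided: bool = True,
) -> list[ImpactRecord]:
    """Build impact records from fitted protein curves at both temperatures.

    The slope per temperature is the mean over replicates. With
    ``two_sided`` (default) the hit rule reads the threshold as a magnitude,
    |slope| > threshold on either axis; one-sided compares the signed slope.
    """
    kinase_set = set(kinases)
    slopes: dict[str, dict[int, list[float]]] = defaultdict(lambda: defaultdict(list))
    genes: dict[str, str] = {}
    for ec in entity_curves:
        slopes[ec.entity_id][ec.temperature].append(ec.curve.average_slope)
        genes.setdefault(ec.entity_id, ec.gene)
    records = []
    for protein in sorted(slopes):
        by_temp = slopes[protein]
        s37 = float(np.mean(by_temp[37])) if by_temp.get(37) else math.nan
        s52 = float(np.mean(by_temp[52])) if by_temp.get(52) else math.nan
        values = [s for s in (s37, s52) if not math.isnan(s)]
        if two_sided:
            is_hit = any(abs(s) > hit_threshold for s in values)
        else:
            is_hit = any(s > hit_threshold for s in values)
        records.append(ImpactRecord(
            protein_id=protein, gene=genes[protein], slope_37=s37, slope_52=s52,
            is_kinase=protein in kinase_set, is_hit=is_hit,
        ))
    return records


def phospho_response(site_calls: Sequence[SiteCall]) -> pd.DataFrame:
    """One row per site: per-replicate calls, final category, mean slope and
    the upward-interval metric (the phospho-response scatter's x-axis)."""
    rows = []
    for call in site_calls:
        rows.append({
            "site_id": call.entity_id,
            "protein_id": call.protein_id,
            "gene": call.gene,
            "rep1_category": call.rep_categories[0].value,
            "rep1_slope": call.rep_curves[0].average_slope,
            "rep2_category": call.rep_categories[1].value,
            "rep2_slope": call.rep_curves[1].average_slope,
            "final_category": call.final_category.value,
            "mean_slope": call.mean_average_slope,
            "upward_intervals": call.upward_intervals,
        })
    columns = ["site_id", "protein_id", "gene", "rep1_category", "rep1_slope",
               "rep2_category", "rep2_slope", "final_category", "mean_slope",
               "upward_intervals"]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("site_id", kind="mergesort").reset_index(drop=True)


def category_proportions(table: pd.DataFrame) -> dict[str, Fraction]:
    """Global category proportions (the pie chart).

    Returned as exact rationals so they always sum to 1; they compare
    equal to floats (``Fraction(1, 4) == 0.25``)."""
    if table.empty:
        return {}
    counts = table["final_category"].value_counts()
    total = int(counts.sum())
    return {cat: Fraction(int(n), total) for cat, n in counts.items()}


def heterogeneity_summary(site_calls: Sequence[SiteCall]) -> HeterogeneitySummary:
    """Bucket proteins by the exact set of non-NR categories among their sites."""
    per_protein: dict[str, set[ResponseCategory]] = defaultdict(set)
    for call in site_calls:
        if call.final_category is not ResponseCategory.NR:
            per_protein[call.protein_id].add(call.final_category)
    frozen = {p: frozenset(cats) for p, cats in per_protein.items()}
    counts: dict[frozenset, int] = defaultdict(int)
    for cats in frozen.values():
        counts[cats] += 1
    return HeterogeneitySummary(per_protein=frozen, combination_counts=dict(counts))


def hypergeom_enrichment(
    hit_ids: Iterable[str],
    background_ids: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per gene set.

    With N background identifiers, n hits, K set members in the background
    and k of those among the hits, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    Sets are intersected with the background before testing; a hit missing
    from the background is an input error.
    """
    hits = set(hit_ids)
    background = set(background_ids)
    stray = hits - background
    if stray:
        raise InputError(f"hit identifier not in background: {sorted(stray)[0]}")
    n_hits, n_bg = len(hits), len(background)
    names = sorted(gene_sets)
    raw = []
    for name in names:
        members = set(gene_sets[name]) & background
        k = len(members & hits)
        p = float(hypergeom.sf(k - 1, n_bg, len(members), n_hits))
        raw.append((name, k, len(members), min(p, 1.0)))
    if raw:
        fdr = multipletests([r[3] for r in raw], method="fdr_bh")[1]
    else:
        fdr = []
    return [
        EnrichmentResult(set_name=name, overlap_k=k, set_size_K=K, hits_n=n_hits,
                         background_N=n_bg, p_value=p, bh_fdr=float(q),
                         significant=p < alpha)
        for (name, k, K, p), q in zip(raw, fdr)
    ]
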