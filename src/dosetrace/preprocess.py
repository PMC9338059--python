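"""Filtering, aggregation and normalization of quantification rows.

Turns validated quantification rows into per-entity dose traces on the
ordinal position axis. The pipeline order is fixed:

1. localization filter (sites only) and collapse of multiplicity variants,
2. rows -> traces, dropping globally excluded outlier positions,
3. completeness filter (all retained dose points > 0 in both replicates,
   evaluated per temperature),
4. first-dose normalization (divide by the first retained dose's value).

Protein tables are channel-wise summed over their peptide rows before
normalization ("aggregate then normalize"): summing fold changes would
weight peptides equally regardless of abundance, which is not what a
summarised protein abundance means.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateTraceError, InputError
from .io import DoseDesign, ProteinQuantRow, SiteQuantRow

logger = logging.getLogger("dosetrace")


@dataclass(frozen=True)
class DoseTrace:
    """One entity's abundances along the dose ladder.

    ``x`` holds the original ordinal position labels (excluded positions
    simply disappear from the grid, surviving labels are preserved), ``y``
    the abundances — arbitrary reporter-ion units before normalization,
    fold changes relative to the first dose after.
    """

    entity_id: str
    replicate_id: int
    temperature: int
    x: tuple[int, ...]
    y: tuple[float, ...]
    normalized: bool = False
    gene: str = ""

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise InputError(f"{self.entity_id}: x and y lengths differ")
        if len(self.y) < 3:
            raise DegenerateTraceError(
                f"{self.entity_id}: trace has {len(self.y)} points, need >= 3"
            )
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise InputError(f"{self.entity_id}: positions must be strictly increasing")


def filter_localization(rows: Iterable[SiteQuantRow], min_prob: float) -> list[SiteQuantRow]:
    """Keep sites with localization probability >= ``min_prob``.

    The boundary is kept: the published rule removes sites with probability
    strictly lower than the floor.
    """
    if not 0.0 <= min_prob <= 1.0:
        raise InputError(f"min_prob must be in [0, 1], got {min_prob}")
    rows = list(rows)
    kept = [r for r in rows if r.localization_prob >= min_prob]
    removed = len(rows) - len(kept)
    if removed:
        logger.info("localization filter removed %d of %d site rows (< %.2f)",
                    removed, len(rows), min_prob)
    return kept


def collapse_site_variants(rows: Iterable[SiteQuantRow]) -> list[SiteQuantRow]:
    """Collapse multiplicity variants of the same site to the best-localized row.

    Site identity is (protein, position, residue) within one replicate and
    temperature; ties keep the first-seen row (input order is deterministic).
    """
    best: dict[tuple, SiteQuantRow] = {}
    for r in rows:
        key = (r.protein_id, r.site_position, r.residue, r.replicate_id, r.temperature)
        cur = best.get(key)
        if cur is None or r.localization_prob > cur.localization_prob:
            best[key] = r
    return list(best.values())


def site_rows_to_traces(
    rows: Iterable[SiteQuantRow],
    design: DoseDesign,
    excluded_positions: frozenset[int] | set[int] = frozenset(),
) -> list[DoseTrace]:
    """One trace per site row, with excluded outlier positions dropped."""
    traces = []
    for r in rows:
        trace = DoseTrace(
            entity_id=r.site_id, replicate_id=r.replicate_id,
            temperature=r.temperature, x=design.positions, y=r.intensities,
            gene=r.gene,
        )
        traces.append(drop_excluded_positions(trace, excluded_positions))
    return traces


def aggregate_protein(
    rows: Sequence[ProteinQuantRow],
    design: DoseDesign,
    excluded_positions: frozenset[int] | set[int] = frozenset(),
) -> list[DoseTrace]:
    """Channel-wise sum of peptide rows of the same protein.

    Returns one trace per protein x replicate x temperature. The sum is
    order-independent.
    """
    sums: dict[tuple, np.ndarray] = {}
    genes: dict[tuple, str] = {}
    for r in rows:
        key = (r.protein_id, r.replicate_id, r.temperature)
        if key in sums:
            sums[key] = sums[key] + np.asarray(r.intensities)
        else:
            sums[key] = np.asarray(r.intensities, dtype=float)
            genes[key] = r.gene
    out = []
    for (protein, rep, temp), y in sorted(sums.items()):
        trace = DoseTrace(entity_id=protein, replicate_id=rep, temperature=temp,
                          x=design.positions, y=tuple(y), gene=genes[(protein, rep, temp)])
        out.append(drop_excluded_positions(trace, excluded_positions))
    return out


def drop_excluded_positions(
    trace: DoseTrace, excluded_positions: frozenset[int] | set[int]
) -> DoseTrace:
    """Remove user-specified outlier positions, preserving surviving labels."""
    if not excluded_positions:
        return trace
    keep = [i for i, pos in enumerate(trace.x) if pos not in excluded_positions]
    if len(keep) < 3:
        raise DegenerateTraceError(
            f"{trace.entity_id}: only {len(keep)} points survive exclusion, need >= 3"
        )
    if len(keep) == len(trace.x):
        return trace
    return replace(trace,
                   x=tuple(trace.x[i] for i in keep),
                   y=tuple(trace.y[i] for i in keep))


def filter_complete(traces: Iterable[DoseTrace], n_replicates: int = 2) -> list[DoseTrace]:
    """Keep entities with strictly positive values at every retained dose
    point in all ``n_replicates`` replicates.

    Completeness is evaluated per temperature independently: an entity may
    survive at 37 °C and fail at 52 °C, matching the two temperatures being
    analysed as separate curves.
    """
    groups: dict[tuple, list[DoseTrace]] = defaultdict(list)
    for t in traces:
        groups[(t.entity_id, t.temperature)].append(t)
    kept: list[DoseTrace] = []
    n_dropped = 0
    for key in sorted(groups):
        group = groups[key]
        reps = {t.replicate_id for t in group}
        if len(reps) < n_replicates or len(group) != len(reps):
            n_dropped += 1
            continue
        if all(all(v > 0 for v in t.y) for t in group):
            kept.extend(sorted(group, key=lambda t: t.replicate_id))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("completeness filter dropped %d entity x temperature groups", n_dropped)
    return kept


def normalize_first_dose(trace: DoseTrace) -> DoseTrace:
    """Divide the trace by its first retained dose's value (fold change).

    Idempotent; scale-invariant (``c*y`` normalizes identically to ``y``).
    """
    first = trace.y[0]
    if first <= 0:
        raise InputError(
            f"{trace.entity_id}: first dose value is {first}; cannot normalize "
            "(entity should have been removed by the completeness filter)"
        )
    if trace.normalized and first == 1.0:
        return trace
    y = tuple(v / first for v in trace.y)
    return replace(trace, y=y, normalized=True)
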