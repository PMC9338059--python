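"""Response-pattern classification of fitted phosphosite curves.

Each fitted curve is assigned one of four categories — hyper-phosphorylation
(HYPER), hypo-phosphorylation (HYPO), BIPHASIC, or non-responsive (NR) —
from four user-set parameters:

T  minimum fitted fold-change range for a responsive curve,
B  minimum run of consecutive upward trends (hyper; both arms of biphasic),
C  minimum run of consecutive downward trends (hypo),
E  the ends of a biphasic curve must differ by at most E times the range.

The decision procedure, in order:

1. range_fitted <= T                                        -> NR
2. up-run >= B and down-run >= B and end_diff <= E * range  -> BIPHASIC
3. average_slope > 0 and up-run >= B                        -> HYPER
4. average_slope < 0 and down-run >= C                      -> HYPO
5. otherwise                                                -> NR

BIPHASIC is tested before HYPER/HYPO so that a rise-and-fall curve with a
small residual slope is not absorbed into a monotone class. A final
category other than NR requires the two biological replicates to agree;
the reported slope is always the mean of the replicates' average slopes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import InputError, PairingError
from .io import RunConfig
from .smoothing import FittedCurve, run_statistics


class ResponseCategory(str, enum.Enum):
    HYPER = "hyper"
    HYPO = "hypo"
    BIPHASIC = "biphasic"
    NR = "NR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifyParams:
    """The T/C/B/E thresholds plus the two documented rule variants.

    ``biphasic_down_run`` selects whether the downward arm of a biphasic
    curve must reach B (default) or C consecutive trends;``end_rule``
    selects whether the end-difference bound is E times the fitted range
    (default) or E times the threshold T.
    """

    range_t: float = 0.3
    down_run_c: int = 5
    up_run_b: int = 3
    end_factor_e: float = 0.45
    biphasic_down_run: str = "B"
    end_rule: str = "range"

    @classmethod
    def from_config(cls, config: RunConfig) -> "ClassifyParams":
        return cls(range_t=config.range_t, down_run_c=config.down_run_c,
                   up_run_b=config.up_run_b, end_factor_e=config.end_factor_e,
                   biphasic_down_run=config.biphasic_down_run,
                   end_rule=config.end_rule)


@dataclass(frozen=True)
class SiteCall:
    """Final per-site call reconciling the two replicates."""

    entity_id: str
    protein_id: str
    gene: str
    rep_curves: tuple[FittedCurve, FittedCurve]
    rep_categories: tuple[ResponseCategory, ResponseCategory]
    final_category: ResponseCategory
    mean_average_slope: float
    upward_intervals: int


def classify_curve(curve: FittedCurve, params: ClassifyParams) -> ResponseCategory:
    """Assign a response category to one fitted curve (total function)."""
    if curve.range_fitted <= params.range_t:
        return ResponseCategory.NR
    down_req = params.up_run_b if params.biphasic_down_run == "B" else params.down_run_c
    end_bound = (params.end_factor_e * curve.range_fitted
                 if params.end_rule == "range"
                 else params.end_factor_e * params.range_t)
    if (curve.max_up_run >= params.up_run_b
            and curve.max_down_run >= down_req
            and curve.end_diff <= end_bound):
        return ResponseCategory.BIPHASIC
    if curve.average_slope > 0 and curve.max_up_run >= params.up_run_b:
        return ResponseCategory.HYPER
    if curve.average_slope < 0 and curve.max_down_run >= params.down_run_c:
        return ResponseCategory.HYPO
    return ResponseCategory.NR


def upward_interval_metric(curves: tuple[FittedCurve, FittedCurve]) -> int:
    """Longest upward run of the element-wise mean of the replicate fits.

    This is the x-axis of the phospho-response scatter.
    """
    a, b = curves
    if a.x != b.x:
        raise PairingError("replicate curves are on different position grids")
    mean_fit = (np.asarray(a.y_hat) + np.asarray(b.y_hat)) / 2.0
    return run_statistics(mean_fit)[0]


def reconcile_replicates(
    entity_id: str,
    curves: tuple[FittedCurve, FittedCurve],
    params: ClassifyParams,
    *,
    protein_id: str = "",
    gene: str = "",
) -> SiteCall:
    """Combine two replicate fits into a final call.

    The final category is the shared per-replicate category when both
    replicates agree (and it is not NR); any discordance yields NR. The
    site's slope is the arithmetic mean of the replicate average slopes
    regardless of the category outcome.
    """
    if len(curves) != 2:
        raise InputError(
            f"{entity_id}: exactly 2 replicates are supported, got {len(curves)}"
        )
    cats = tuple(classify_curve(c, params) for c in curves)
    final = cats[0] if cats[0] == cats[1] else ResponseCategory.NR
    return SiteCall(
        entity_id=entity_id,
        protein_id=protein_id or entity_id,
        gene=gene,
        rep_curves=curves,
        rep_categories=cats,
        final_category=final,
        mean_average_slope=float(np.mean([c.average_slope for c in curves])),
        upward_intervals=upward_interval_metric(curves),
    )
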