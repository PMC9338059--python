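"""End-to-end pipeline orchestration shared by the CLI and the tests.

Each run produces a result table plus a :class:`RunManifest` recording the
configuration snapshot, input digests and per-stage record counts, so that
identical inputs and configuration always yield identical outputs and the
manifest documents exactly what was kept and dropped at every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import ClassifyParams, reconcile_replicates
from .errors import ConfigError, InputError, PairingError
from .impact import EntityCurve, ImpactRecord, phospho_response, proteome_impact
from .io import (ProteinQuantRow, RunConfig, SiteQuantRow, config_to_mapping,
                 read_protein_table, read_site_table)
from .preprocess import (aggregate_protein, collapse_site_variants,
                         filter_complete, filter_localization,
                         normalize_first_dose, site_rows_to_traces)
from .smoothing import fit_trace

logger = logging.getLogger("dosetrace")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    command: str
    version: str = __version__
    timestamp: str = ""
    config: dict = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n",
                              encoding="utf-8")


def _digest(path) -> str:
    h = hashlib.sha256()
    try:
        h.update(Path(path).read_bytes())
    except OSError as exc:
        raise InputError(f"cannot read input file {path}: {exc}") from None
    return h.hexdigest()


def _manifest(command: str, config: RunConfig, paths) -> RunManifest:
    return RunManifest(
        command=command,
        config=config_to_mapping(config),
        input_digests={str(p): _digest(p) for p in paths},
    )


def run_phospho(
    config: RunConfig, site_tables: list, *, replicate_ids: list[int] | None = None,
    temperature: int = 37,
) -> tuple[pd.DataFrame, RunManifest]:
    """Phosphosite pipeline: read -> filter -> fit -> classify -> reconcile.

    ``site_tables`` is either one file carrying a Replicate column or two
    files (one per replicate, optionally labelled via ``replicate_ids``).
    """
    manifest = _manifest("phospho", config, site_tables)
    rows: list[SiteQuantRow] = []
    n_rejected = 0
    if len(site_tables) == 1:
        parsed, report = read_site_table(site_tables[0], config.design,
                                         temperature=temperature, columns=config.columns)
        rows.extend(parsed)
        n_rejected += report.n_rejected
    elif len(site_tables) == 2:
        reps = replicate_ids or [1, 2]
        for path, rep in zip(site_tables, reps):
            parsed, report = read_site_table(path, config.design, replicate_id=rep,
                                             temperature=temperature, columns=config.columns)
            rows.extend(parsed)
            n_rejected += report.n_rejected
    else:
        raise ConfigError(f"expected 1 or 2 site tables, got {len(site_tables)}")
    rows = [r for r in rows if r.temperature == temperature]
    manifest.counts["parsed"] = len(rows)
    manifest.counts["rejected_rows"] = n_rejected

    rows = filter_localization(rows, config.min_localization)
    manifest.counts["after_localization_filter"] = len(rows)
    rows = collapse_site_variants(rows)
    manifest.counts["after_variant_collapse"] = len(rows)

    replicates = sorted({r.replicate_id for r in rows})
    if rows and len(replicates) != 2:
        raise ConfigError(f"exactly 2 replicates required, found {replicates}")

    traces = site_rows_to_traces(rows, config.design, config.excluded_positions)
    traces = filter_complete(traces, n_replicates=2)
    manifest.counts["entities_complete"] = len(traces) // 2

    params = ClassifyParams.from_config(config)
    by_entity: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for trace in traces:
        fitted = fit_trace(normalize_first_dose(trace), config)
        by_entity.setdefault(trace.entity_id, []).append((trace.replicate_id, fitted))
        protein = trace.entity_id.rsplit("_", 1)[0]
        meta[trace.entity_id] = (protein, trace.gene)
    calls = []
    for entity_id in sorted(by_entity):
        pair = sorted(by_entity[entity_id])
        if len(pair) != 2:
            raise PairingError(f"{entity_id}: expected 2 replicate curves, got {len(pair)}")
        protein, gene = meta[entity_id]
        calls.append(reconcile_replicates(
            entity_id, (pair[0][1], pair[1][1]), params, protein_id=protein, gene=gene))

    table = phospho_response(calls)
    for cat, n in Counter(c.final_category.value for c in calls).items():
        manifest.counts[f"category_{cat}"] = n
    manifest.counts["classified"] = len(calls)
    return table, manifest


def run_proteome(
    config: RunConfig, protein_tables: list, *,
    labels: list[tuple[int, int]] | None = None, kinases=(),
) -> tuple[pd.DataFrame, RunManifest]:
    """Protein pipeline producing the proteome-impact table.

    ``labels`` gives (temperature, replicate) per file for tables without
    Temperature/Replicate columns.
    """
    manifest = _manifest("proteome", config, protein_tables)
    rows: list[ProteinQuantRow] = []
    n_rejected = 0
    for i, path in enumerate(protein_tables):
        temp = rep = None
        if labels is not None:
            temp, rep = labels[i]
        parsed, report = read_protein_table(path, config.design, replicate_id=rep,
                                            temperature=temp, columns=config.columns,
                                            kinases=kinases)
        rows.extend(parsed)
        n_rejected += report.n_rejected
    manifest.counts["parsed"] = len(rows)
    manifest.counts["rejected_rows"] = n_rejected

    traces = aggregate_protein(rows, config.design, config.excluded_positions)
    traces = filter_complete(traces, n_replicates=2)
    manifest.counts["entity_temperature_groups_complete"] = (
        len({(t.entity_id, t.temperature) for t in traces}))

    entity_curves = []
    for trace in traces:
        fitted = fit_trace(normalize_first_dose(trace), config)
        entity_curves.append(EntityCurve(
            entity_id=trace.entity_id, gene=trace.gene,
            temperature=trace.temperature, replicate_id=trace.replicate_id,
            curve=fitted))
    records = proteome_impact(entity_curves, config.hit_threshold,
                              kinases=kinases, two_sided=config.hit_two_sided)
    manifest.counts["proteins"] = len(records)
    manifest.counts["hits"] = sum(r.is_hit for r in records)
    df = pd.DataFrame([{
        "protein_id": r.protein_id, "gene": r.gene, "slope_37": r.slope_37,
        "slope_52": r.slope_52, "is_kinase": r.is_kinase, "is_hit": r.is_hit,
    } for r in records], columns=["protein_id", "gene", "slope_37", "slope_52",
                                  "is_kinase", "is_hit"])
    return df.sort_values("protein_id", kind="mergesort").reset_index(drop=True), manifest


def impact_records_from_table(df: pd.DataFrame) -> list[ImpactRecord]:
    """Rehydrate impact records from a written result table."""
    out = []
    for row in df.itertuples(index=False):
        out.append(ImpactRecord(
            protein_id=str(row.protein_id), gene="" if pd.isna(row.gene) else str(row.gene),
            slope_37=float(row.slope_37) if pd.notna(row.slope_37) else float("nan"),
            slope_52=float(row.slope_52) if pd.notna(row.slope_52) else float("nan"),
            is_kinase=bool(row.is_kinase), is_hit=bool(row.is_hit)))
    return out
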