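"""Reading and writing quantitative proteomics tables and run configuration.

Input tables follow a MaxQuant-like layout: one tab-separated file with a
header row, one reporter-intensity column per channel, and (for phosphosite
tables) localization probability, protein accession, site position and
amino-acid columns. Files may either carry explicit ``Replicate`` and
``Temperature`` columns, or the caller supplies those as file-level metadata
(the one-file-per-condition layout used by search-engine exports).

Validation is total: every input row is either parsed into a typed record or
produces a named diagnostic in the :class:`ReadReport`; nothing is silently
dropped.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DesignError, InputError, SchemaError

logger = logging.getLogger("dosetrace")

#: Reference role marker in a channel map.
REFERENCE = "reference"

#: The staurosporine dose ladder, in µM, vehicle first.
DEFAULT_DOSES: tuple[float, ...] = (
    0.0, 0.0024, 0.0098, 0.0390, 0.1563, 0.6250, 2.5, 5.0, 10.0,
)

VALID_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class DoseDesign:
    """The dose ladder and its mapping to reporter channels.

    Concentrations are carried for reporting, but curve fitting happens on
    the ordinal positions 1..n of the sorted ladder: the ladder spans five
    orders of magnitude plus a zero dose, so an ordinal axis spaces the
    observations evenly and keeps the kernel bandwidth meaningful.

    Parameters
    ----------
    doses
        Nondecreasing concentrations, first entry the vehicle (zero) dose.
    channel_map
        Mapping from reporter-channel label to a 0-based dose index, or to
        the special role ``"reference"`` for a cross-plex reference channel
        that takes no part in curve fitting.
    """

    doses: tuple[float, ...] = DEFAULT_DOSES
    channel_map: Mapping[str, int | str] | None = None

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        if len(doses) < 3:
            raise ConfigError(f"dose design needs at least 3 doses, got {len(doses)}")
        if any(b < a for a, b in zip(doses, doses[1:])):
            raise ConfigError("doses must be nondecreasing")
        if self.channel_map is None:
            cmap: dict[str, int | str] = {str(i + 1): i for i in range(len(doses))}
            object.__setattr__(self, "channel_map", cmap)
        indices = sorted(v for v in self.channel_map.values() if v != REFERENCE)
        if indices != list(range(len(doses))):
            raise ConfigError(
                "channel_map must assign each dose index 0..n-1 to exactly one "
                f"non-reference channel; got indices {indices} for n={len(doses)}"
            )

    @property
    def n(self) -> int:
        return len(self.doses)

    @property
    def positions(self) -> tuple[int, ...]:
        """Ordinal x-positions 1..n, one per dose in ladder order."""
        return tuple(range(1, len(self.doses) + 1))

    @property
    def dose_channels(self) -> tuple[str, ...]:
        """Channel labels in dose order (reference channels excluded)."""
        by_index = {v: k for k, v in self.channel_map.items() if v != REFERENCE}
        return tuple(by_index[i] for i in range(self.n))


@dataclass(frozen=True)
class ColumnSchema:
    """Configurable column names with MaxQuant-like defaults."""

    protein: str = "Protein"
    gene: str = "Gene names"
    position: str = "Position"
    amino_acid: str = "Amino acid"
    localization: str = "Localization prob"
    intensity_template: str = "Reporter intensity corrected {channel}"
    replicate: str = "Replicate"
    temperature: str = "Temperature"

    def intensity(self, channel: str) -> str:
        return self.intensity_template.format(channel=channel)


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a run.

    ``bandwidth`` is on the ordinal-position scale. ``range_t`` (T) is the
    minimum fitted fold-change range for a responsive curve; ``up_run_b``
    (B) and ``down_run_c`` (C) are the minimum lengths of consecutive
    upward / downward trends for hyper- and hypo-phosphorylation;
    ``end_factor_e`` (E) bounds the difference between the curve's ends for
    a biphasic call. Defaults follow the published staurosporine analysis
    (T, C, B, E = 0.3, 5, 3, 0.45) with a hit threshold of 0.5 on the
    average slope and a 50% localization-probability floor.
    """

    design: DoseDesign = field(default_factory=DoseDesign)
    bandwidth: float = 1.0
    range_t: float = 0.3
    down_run_c: int = 5
    up_run_b: int = 3
    end_factor_e: float = 0.45
    hit_threshold: float = 0.5
    min_localization: float = 0.5
    excluded_positions: frozenset[int] = frozenset()
    biphasic_down_run: str = "B"   # "B" (default) or "C"
    end_rule: str = "range"        # end_diff <= E*range ("range") or E*T ("threshold")
    hit_two_sided: bool = True
    columns: ColumnSchema = field(default_factory=ColumnSchema)

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ConfigError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.range_t <= 0:
            raise ConfigError(f"T (range_t) must be > 0, got {self.range_t}")
        if self.up_run_b < 1 or self.down_run_c < 1:
            raise ConfigError("B and C must be integers >= 1")
        if not 0 <= self.end_factor_e <= 1:
            raise ConfigError(f"E (end_factor_e) must be in [0, 1], got {self.end_factor_e}")
        if self.hit_threshold <= 0:
            raise ConfigError(f"hit_threshold must be > 0, got {self.hit_threshold}")
        if not 0 <= self.min_localization <= 1:
            raise ConfigError("min_localization must be in [0, 1]")
        if self.biphasic_down_run not in ("B", "C"):
            raise ConfigError("biphasic_down_run must be 'B' or 'C'")
        if self.end_rule not in ("range", "threshold"):
            raise ConfigError("end_rule must be 'range' or 'threshold'")
        object.__setattr__(self, "excluded_positions", frozenset(int(p) for p in self.excluded_positions))
        bad = self.excluded_positions - set(self.design.positions)
        if bad:
            raise ConfigError(f"excluded_positions {sorted(bad)} not in design positions")


@dataclass(frozen=True)
class SiteQuantRow:
    """One phosphosite quantification in one replicate at one temperature."""

    protein_id: str
    gene: str
    site_position: int
    residue: str
    localization_prob: float
    replicate_id: int
    temperature: int
    intensities: tuple[float, ...]

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}_{self.residue}{self.site_position}"


@dataclass(frozen=True)
class ProteinQuantRow:
    """One protein(-group) quantification in one replicate at one temperature."""

    protein_id: str
    gene: str
    is_kinase: bool
    replicate_id: int
    temperature: int
    intensities: tuple[float, ...]


@dataclass
class ReadReport:
    """Accounting for one table read: parsed + rejected == total rows."""

    path: str
    n_rows: int = 0
    n_parsed: int = 0
    n_rejected: int = 0
    diagnostics: list[str] = field(default_factory=list)

    def reject(self, message: str) -> None:
        self.n_rejected += 1
        self.diagnostics.append(message)
        logger.warning("%s: %s", self.path, message)


def _read_table(path, columns: ColumnSchema, design: DoseDesign, mandatory: Sequence[str]):
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except FileNotFoundError:
        raise InputError(f"input file not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header row)") from None
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column '{col}'")
    int_cols = [columns.intensity(ch) for ch in design.dose_channels]
    missing = [c for c in int_cols if c not in df.columns]
    if missing:
        present = [c for c in df.columns if c.startswith(columns.intensity_template.split("{")[0])]
        if present and len(present) != design.n:
            raise DesignError(
                f"{path}: found {len(present)} intensity columns but the dose "
                f"design has {design.n} channels"
            )
        raise SchemaError(f"{path}: missing mandatory column '{missing[0]}'")
    return df, int_cols


def _row_meta(row, columns, replicate_id, temperature, report, idx):
    """Resolve replicate/temperature from columns or file-level metadata."""
    rep, temp = replicate_id, temperature
    if columns.replicate in row.index and pd.notna(row[columns.replicate]):
        rep = int(float(row[columns.replicate]))
    if columns.temperature in row.index and pd.notna(row[columns.temperature]):
        temp = int(float(row[columns.temperature]))
    if rep is None or temp is None:
        report.reject(f"row {idx}: replicate/temperature not given in file or arguments")
        return None
    return rep, temp


def _row_intensities(row, int_cols, design, report, idx):
    values = []
    for ch, col in zip(design.dose_channels, int_cols):
        raw = row[col]
        try:
            v = float(raw)
        except (TypeError, ValueError):
            report.reject(f"row {idx}: non-numeric intensity in channel {ch} ({raw!r})")
            return None
        if not np.isfinite(v):
            report.reject(f"row {idx}: non-finite intensity in channel {ch}")
            return None
        if v < 0:
            report.reject(f"row {idx}: negative intensity in channel {ch} ({v})")
            return None
        values.append(v)
    return tuple(values)


def read_site_table(
    path,
    design: DoseDesign,
    *,
    replicate_id: int | None = None,
    temperature: int | None = None,
    columns: ColumnSchema | None = None,
) -> tuple[list[SiteQuantRow], ReadReport]:
    """Read a phosphosite quantification table.

    Returns the parsed rows and a :class:`ReadReport`; malformed rows are
    counted and reported with the offending row and field named.
    """
    columns = columns or ColumnSchema()
    mandatory = [columns.protein, columns.position, columns.amino_acid, columns.localization]
    df, int_cols = _read_table(path, columns, design, mandatory)
    report = ReadReport(path=str(path), n_rows=len(df))
    out: list[SiteQuantRow] = []
    for idx, row in df.iterrows():
        meta = _row_meta(row, columns, replicate_id, temperature, report, idx)
        if meta is None:
            continue
        rep, temp = meta
        try:
            pos = int(float(row[columns.position]))
            prob = float(row[columns.localization])
        except (TypeError, ValueError):
            report.reject(f"row {idx}: non-numeric position or localization probability")
            continue
        residue = str(row[columns.amino_acid]).strip()
        if pos < 1:
            report.reject(f"row {idx}: site position must be >= 1, got {pos}")
            continue
        if residue not in VALID_RESIDUES:
            report.reject(f"row {idx}: amino acid must be one of S/T/Y, got {residue!r}")
            continue
        if not 0.0 <= prob <= 1.0:
            report.reject(f"row {idx}: localization probability {prob} outside [0, 1]")
            continue
        intensities = _row_intensities(row, int_cols, design, report, idx)
        if intensities is None:
            continue
        gene = "" if columns.gene not in row.index or pd.isna(row[columns.gene]) else str(row[columns.gene])
        out.append(SiteQuantRow(
            protein_id=str(row[columns.protein]), gene=gene, site_position=pos,
            residue=residue, localization_prob=prob, replicate_id=rep,
            temperature=temp, intensities=intensities,
        ))
        report.n_parsed += 1
    if report.n_rows == 0:
        logger.warning("%s: table contains no data rows", path)
    return out, report


def read_protein_table(
    path,
    design: DoseDesign,
    *,
    replicate_id: int | None = None,
    temperature: int | None = None,
    columns: ColumnSchema | None = None,
    kinases: Iterable[str] = (),
) -> tuple[list[ProteinQuantRow], ReadReport]:
    """Read a protein(-group) quantification table.

    ``kinases`` is a user-supplied collection of accessions; matching rows
    get ``is_kinase=True`` (annotation only — it never affects computation).
    """
    columns = columns or ColumnSchema()
    kinase_set = set(kinases)
    df, int_cols = _read_table(path, columns, design, [columns.protein])
    report = ReadReport(path=str(path), n_rows=len(df))
    out: list[ProteinQuantRow] = []
    for idx, row in df.iterrows():
        meta = _row_meta(row, columns, replicate_id, temperature, report, idx)
        if meta is None:
            continue
        rep, temp = meta
        intensities = _row_intensities(row, int_cols, design, report, idx)
        if intensities is None:
            continue
        protein = str(row[columns.protein])
        gene = "" if columns.gene not in row.index or pd.isna(row[columns.gene]) else str(row[columns.gene])
        out.append(ProteinQuantRow(
            protein_id=protein, gene=gene, is_kinase=protein in kinase_set,
            replicate_id=rep, temperature=temp, intensities=intensities,
        ))
        report.n_parsed += 1
    if report.n_rows == 0:
        logger.warning("%s: table contains no data rows", path)
    return out, report


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a two-column TSV (set name, member); duplicates are deduplicated."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SchemaError(f"{path}: line {lineno}: expected two tab-separated columns")
            sets.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return sets


def read_kinase_list(path) -> set[str]:
    """Read a one-accession-per-line kinase annotation list."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def read_id_list(path) -> list[str]:
    """Read a one-identifier-per-line list, preserving order, deduplicated."""
    seen: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            ident = line.strip()
            if ident and not ident.startswith("#"):
                seen.setdefault(ident, None)
    return list(seen)


# ---------------------------------------------------------------------------
# Run configuration files: a flat YAML mapping.

_CONFIG_KEYS = {
    "doses", "channel_map", "bandwidth", "T", "C", "B", "E", "hit_threshold",
    "min_localization", "excluded_positions", "biphasic_down_run", "end_rule",
    "hit_two_sided", "columns",
}


def read_config(path) -> RunConfig:
    """Read a flat key-value run configuration file (YAML mapping).

    Recognised keys: doses, channel_map, bandwidth, T, C, B, E,
    hit_threshold, min_localization, excluded_positions, biphasic_down_run,
    end_rule, hit_two_sided, columns (a sub-mapping of column names).
    """
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed config file: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    return config_from_mapping(raw)


def config_from_mapping(raw: Mapping) -> RunConfig:
    design_kwargs = {}
    if "doses" in raw:
        doses = raw["doses"]
        if isinstance(doses, str):
            doses = [float(d) for d in doses.replace(",", " ").split()]
        design_kwargs["doses"] = tuple(float(d) for d in doses)
    if "channel_map" in raw:
        cmap = dict(raw["channel_map"])
        design_kwargs["channel_map"] = {
            str(k): (v if v == REFERENCE else int(v)) for k, v in cmap.items()
        }
    kwargs: dict = {"design": DoseDesign(**design_kwargs)}
    scalar = {
        "bandwidth": ("bandwidth", float), "T": ("range_t", float),
        "C": ("down_run_c", int), "B": ("up_run_b", int),
        "E": ("end_factor_e", float), "hit_threshold": ("hit_threshold", float),
        "min_localization": ("min_localization", float),
        "biphasic_down_run": ("biphasic_down_run", str), "end_rule": ("end_rule", str),
        "hit_two_sided": ("hit_two_sided", bool),
    }
    for key, (attr, cast) in scalar.items():
        if key in raw:
            try:
                kwargs[attr] = cast(raw[key])
            except (TypeError, ValueError):
                raise ConfigError(f"config key {key!r}: cannot parse {raw[key]!r}") from None
    if "excluded_positions" in raw:
        excl = raw["excluded_positions"]
        if isinstance(excl, str):
            excl = [int(p) for p in excl.replace(",", " ").split()]
        kwargs["excluded_positions"] = frozenset(int(p) for p in excl)
    if "columns" in raw:
        cols = raw["columns"]
        valid = {f.name for f in fields(ColumnSchema)}
        unknown = set(cols) - valid
        if unknown:
            raise ConfigError(f"unknown column-schema keys: {sorted(unknown)}")
        kwargs["columns"] = ColumnSchema(**{k: str(v) for k, v in cols.items()})
    return RunConfig(**kwargs)


def config_to_mapping(config: RunConfig) -> dict:
    """Serialise a RunConfig to the flat mapping accepted by read_config."""
    return {
        "doses": list(config.design.doses),
        "channel_map": dict(config.design.channel_map),
        "bandwidth": config.bandwidth,
        "T": config.range_t,
        "C": config.down_run_c,
        "B": config.up_run_b,
        "E": config.end_factor_e,
        "hit_threshold": config.hit_threshold,
        "min_localization": config.min_localization,
        "excluded_positions": sorted(config.excluded_positions),
        "biphasic_down_run": config.biphasic_down_run,
        "end_rule": config.end_rule,
        "hit_two_sided": config.hit_two_sided,
        "columns": {f.name: getattr(config.columns, f.name) for f in fields(ColumnSchema)},
    }


# ---------------------------------------------------------------------------
# Result tables.

RESULT_COLUMNS = {
    "impact": ["protein_id", "gene", "slope_37", "slope_52", "is_kinase", "is_hit"],
    "phospho": [
        "site_id", "protein_id", "gene", "rep1_category", "rep1_slope",
        "rep2_category", "rep2_slope", "final_category", "mean_slope",
        "upward_intervals",
    ],
    "enrichment": [
        "set_name", "overlap_k", "set_size_K", "hits_n", "background_N",
        "p_value", "bh_fdr", "significant",
    ],
}

_FLOAT_COLUMNS = {"slope_37", "slope_52", "rep1_slope", "rep2_slope",
                  "mean_slope", "p_value", "bh_fdr"}


def write_results(records, path, kind: str) -> None:
    """Write a result table as TSV with deterministic column and row order.

    ``records`` may be a DataFrame or an iterable of dataclass records.
    Numeric fields are written at 8 significant digits so a write/read
    round-trip reproduces them within 1e-6 relative tolerance.
    """
    if kind not in RESULT_COLUMNS:
        raise ValueError(f"unknown result kind {kind!r}")
    cols = RESULT_COLUMNS[kind]
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([_record_to_dict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(columns=cols)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"result records missing columns {missing}")
    df = df[cols].sort_values(cols[0], kind="mergesort").reset_index(drop=True)
    for c in df.columns:
        if c in _FLOAT_COLUMNS:
            df[c] = [("" if pd.isna(v) else f"{float(v):.8g}") for v in df[c]]
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise InputError(f"cannot write results to {path}: {exc}") from None


def read_results(path, kind: str) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    if kind not in RESULT_COLUMNS:
        raise ValueError(f"unknown result kind {kind!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing result column '{missing[0]}'")
    return df


def _record_to_dict(rec) -> dict:
    if isinstance(rec, dict):
        return rec
    return {f.name: getattr(rec, f.name) for f in fields(rec)}
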