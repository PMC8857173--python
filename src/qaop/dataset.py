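"""Compound-level dataset: schema, I/O, validation, EDA and design matrices.

The dataset mirrors the tabular evidence base of a simplified adverse outcome
pathway (AOP) for developmental neurotoxicity (DNT): per compound, an in vivo
DNT classification (the adverse outcome, always observed), physicochemical /
ADMET predictors feeding the molecular-level key event (reduction of BDNF), and
two in vitro assay blocks (synaptogenesis imaging, microelectrode-array neural
network formation) feeding the downstream key events. Missing evidence —
absent literature labels, inorganics outside the in silico models' domain,
assay inactives treated as uninformative — is encoded as empty CSV cells and
carried through as explicit masks; nothing in this module imputes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "BINARY_COLUMNS",
    "CONTINUOUS_COLUMNS",
    "LOG10_COLUMNS",
    "CompoundRecord",
    "DNTDataset",
    "DesignMatrices",
    "EdaReport",
    "PredictorAssignment",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "build_design_matrices",
    "explore_dataset",
]

#: CSV header, fixed order.
COLUMNS = (
    "compound_name",
    "cas_rn",
    "smiles",
    "dtxsid",
    "dnt_label",
    "logd",
    "bbb",
    "cbrain_cblood",
    "pgp_substrate",
    "pgp_inhibitor",
    "pgp_active",
    "bdnf_label",
    "syn_label",
    "syn_viability",
    "syn_ec30_um",
    "nnf_label",
    "nnf_viability",
    "nnf_ec50min_um",
    "nnf_ec50max_um",
)

TEXT_COLUMNS = ("compound_name", "cas_rn", "smiles", "dtxsid")
BINARY_COLUMNS = (
    "dnt_label",
    "bbb",
    "pgp_substrate",
    "pgp_inhibitor",
    "pgp_active",
    "bdnf_label",
    "syn_label",
    "nnf_label",
)
CONTINUOUS_COLUMNS = (
    "logd",
    "cbrain_cblood",
    "syn_viability",
    "syn_ec30_um",
    "nnf_viability",
    "nnf_ec50min_um",
    "nnf_ec50max_um",
)
#: effective concentrations span orders of magnitude (µM); log10 before z-scoring
LOG10_COLUMNS = ("syn_ec30_um", "nnf_ec50min_um", "nnf_ec50max_um")

# CSV column -> CompoundRecord attribute
_COL2ATTR = {
    "compound_name": "name",
    "cas_rn": "cas_rn",
    "smiles": "smiles",
    "dtxsid": "dtxsid",
    "dnt_label": "dnt_label",
    "logd": "logd",
    "bbb": "bbb",
    "cbrain_cblood": "cbrain_cblood",
    "pgp_substrate": "pgp_substrate",
    "pgp_inhibitor": "pgp_inhibitor",
    "pgp_active": "pgp_active",
    "bdnf_label": "bdnf_label",
    "syn_label": "syn_label",
    "syn_viability": "syn_viability",
    "syn_ec30_um": "syn_ec30",
    "nnf_label": "nnf_label",
    "nnf_viability": "nnf_viability",
    "nnf_ec50min_um": "nnf_ec50min",
    "nnf_ec50max_um": "nnf_ec50max",
}
_ATTR2COL = {v: k for k, v in _COL2ATTR.items()}


class SchemaError(ValueError):
    """CSV header does not match the documented schema."""


class ParseError(ValueError):
    """A cell value cannot be interpreted under its column's type."""


class DatasetValidationError(ValueError):
    """Dataset violates an invariant that blocks further processing."""


@dataclass
class CompoundRecord:
    """One compound: identifiers, predictors and (possibly missing) labels.

    ``None`` means missing.  ``dnt_label`` (the in vivo adverse-outcome
    classification) is mandatory; EC values are µM and must be positive.
    """

    name: str
    cas_rn: str
    dnt_label: int
    smiles: str | None = None
    dtxsid: str | None = None
    logd: float | None = None
    bbb: int | None = None
    cbrain_cblood: float | None = None
    pgp_substrate: int | None = None
    pgp_inhibitor: int | None = None
    pgp_active: int | None = None
    bdnf_label: int | None = None
    syn_label: int | None = None
    syn_viability: float | None = None
    syn_ec30: float | None = None
    nnf_label: int | None = None
    nnf_viability: float | None = None
    nnf_ec50min: float | None = None
    nnf_ec50max: float | None = None

    def get(self, column: str):
        return getattr(self, _COL2ATTR[column])


@dataclass
class DNTDataset:
    """Ordered compound records; index i (0-based) is stable across the pipeline."""

    records: list[CompoundRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def column(self, name: str) -> np.ndarray:
        """Column as a float array with NaN for missing (binary as 0.0/1.0)."""
        vals = [r.get(name) for r in self.records]
        return np.array([np.nan if v is None else float(v) for v in vals])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({c: r.get(c) for c in COLUMNS})
        return pd.DataFrame(rows, columns=list(COLUMNS))


@dataclass
class PredictorAssignment:
    """Which raw columns feed each key event's design-matrix block.

    Defaults follow the AOP levels: chemical/ADMET properties feed the
    molecular key event (BDNF reduction); each in vitro assay's viability and
    effective-concentration readouts feed its own key event.  ``"intercept"``
    denotes a constant-1 column (never standardized).  Overridable via config.
    """

    bdnf: tuple[str, ...] = (
        "intercept",
        "logd",
        "bbb",
        "cbrain_cblood",
        "pgp_substrate",
        "pgp_inhibitor",
        "pgp_active",
    )
    syn: tuple[str, ...] = ("intercept", "syn_viability", "syn_ec30_um")
    nnf: tuple[str, ...] = (
        "intercept",
        "nnf_viability",
        "nnf_ec50min_um",
        "nnf_ec50max_um",
    )
    include_intercept: bool = True

    def blocks(self) -> dict[str, tuple[str, ...]]:
        out = {}
        for node, cols in (("bdnf", self.bdnf), ("syn", self.syn), ("nnf", self.nnf)):
            if not self.include_intercept:
                cols = tuple(c for c in cols if c != "intercept")
            out[node] = cols
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictorAssignment":
        kw = {}
        for k in ("bdnf", "syn", "nnf"):
            if k in d:
                kw[k] = tuple(d[k])
        if "include_intercept" in d:
            kw["include_intercept"] = bool(d["include_intercept"])
        return cls(**kw)


@dataclass
class DesignMatrices:
    """Standardized per-key-event predictor blocks with missingness masks.

    ``x_*`` hold 0.0 placeholders where the raw value was missing; the
    corresponding ``miss_*`` entry is 1 and the model must not read the
    placeholder.  ``standardization`` maps column label -> (location, scale)
    on the (possibly log10) transformed scale, for round-tripping.
    """

    x_bdnf: np.ndarray
    x_syn: np.ndarray
    x_nnf: np.ndarray
    miss_bdnf: np.ndarray
    miss_syn: np.ndarray
    miss_nnf: np.ndarray
    y_bdnf: np.ndarray
    y_syn: np.ndarray
    y_nnf: np.ndarray
    y_dnt: np.ndarray
    ymiss_bdnf: np.ndarray
    ymiss_syn: np.ndarray
    ymiss_nnf: np.ndarray
    columns: dict[str, tuple[str, ...]]
    standardization: dict[str, tuple[float, float]]
    compound_names: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.x_bdnf.shape[0]

    @property
    def block_dims(self) -> tuple[int, int, int]:
        return (self.x_bdnf.shape[1], self.x_syn.shape[1], self.x_nnf.shape[1])

    def x_blocks(self) -> dict[str, np.ndarray]:
        return {"bdnf": self.x_bdnf, "syn": self.x_syn, "nnf": self.x_nnf}

    def miss_blocks(self) -> dict[str, np.ndarray]:
        return {"bdnf": self.miss_bdnf, "syn": self.miss_syn, "nnf": self.miss_nnf}

    def y_vectors(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """node -> (y, missing_mask); DNT mask is all-zero by invariant."""
        return {
            "bdnf": (self.y_bdnf, self.ymiss_bdnf),
            "syn": (self.y_syn, self.ymiss_syn),
            "nnf": (self.y_nnf, self.ymiss_nnf),
            "dnt": (self.y_dnt, np.zeros_like(self.y_dnt)),
        }


@dataclass
class EdaReport:
    variable_types: dict[str, str]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # col -> (edges, counts)
    pearson_correlations: pd.DataFrame
    missing_fraction: dict[str, float]
    class_balance: dict[str, float]


# ---------------------------------------------------------------------------
# parsing


def _parse_cell(col: str, raw: str, row_idx: int):
    raw = raw.strip()
    if raw == "":
        return None
    if col in TEXT_COLUMNS:
        return raw
    if col in BINARY_COLUMNS:
        if raw in ("0", "1"):
            return int(raw)
        raise ParseError(
            f"row {row_idx}, column '{col}': expected binary 0/1, got {raw!r}"
        )
    try:
        return float(raw)
    except ValueError as exc:
        raise ParseError(
            f"row {row_idx}, column '{col}': expected a real number, got {raw!r}"
        ) from exc


def read_dataset(path: str | Path, provenance: str | None = None) -> DNTDataset:
    """Read the documented CSV dialect into a :class:`DNTDataset`.

    Empty cells become missing values; row order is preserved.  Raises
    :class:`SchemaError` for a wrong header, :class:`ParseError` for a bad
    cell (with row and column), :class:`DatasetValidationError` for duplicate
    CAS RN or a missing mandatory label.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: no header row")
        missing_cols = [c for c in COLUMNS if c not in header]
        if missing_cols:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
        if list(header) != list(COLUMNS):
            extra = [c for c in header if c not in COLUMNS]
            if extra:
                raise SchemaError(f"unknown column(s): {', '.join(extra)}")
            raise SchemaError("columns present but not in the documented order")
        records = []
        for row_idx, row in enumerate(reader, start=1):
            if len(row) != len(COLUMNS):
                raise ParseError(
                    f"row {row_idx}: expected {len(COLUMNS)} fields, got {len(row)}"
                )
            cells = {c: _parse_cell(c, v, row_idx) for c, v in zip(COLUMNS, row)}
            if cells["dnt_label"] is None:
                raise DatasetValidationError(
                    f"row {row_idx}: dnt_label (AO label) is required"
                )
            kw = {_COL2ATTR[c]: v for c, v in cells.items()}
            kw["name"] = kw["name"] or f"compound_{row_idx}"
            records.append(CompoundRecord(**kw))
    ds = DNTDataset(records, provenance=provenance or f"read from {path.name}")
    dups = _duplicate_cas(ds)
    if dups:
        raise DatasetValidationError(f"duplicate CAS RN: {', '.join(sorted(dups))}")
    return ds


def write_dataset(ds: DNTDataset, path: str | Path) -> Path:
    """Write the documented CSV dialect; empty field = missing. Round-trips."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for r in ds.records:
            row = []
            for c in COLUMNS:
                v = r.get(c)
                if v is None:
                    row.append("")
                elif c in BINARY_COLUMNS:
                    row.append(str(int(v)))
                elif c in TEXT_COLUMNS:
                    row.append(str(v))
                else:
                    row.append(repr(float(v)))
            writer.writerow(row)
    return path


def _duplicate_cas(ds: DNTDataset) -> set[str]:
    seen, dups = set(), set()
    for r in ds.records:
        if r.cas_rn in seen:
            dups.add(r.cas_rn)
        seen.add(r.cas_rn)
    return dups


def validate_dataset(ds: DNTDataset) -> list[str]:
    """Return every invariant violation; empty list iff model-ready."""
    violations: list[str] = []
    for i, r in enumerate(ds.records):
        if r.dnt_label is None:
            violations.append(f"record {i}: AO label required (dnt_label missing)")
        for attr in ("syn_ec30", "nnf_ec50min", "nnf_ec50max"):
            v = getattr(r, attr)
            if v is not None and v <= 0:
                violations.append(f"record {i}: non-positive EC ({attr} = {v})")
        if (
            r.nnf_ec50min is not None
            and r.nnf_ec50max is not None
            and r.nnf_ec50min > r.nnf_ec50max
        ):
            violations.append(f"record {i}: nnf_ec50min > nnf_ec50max")
    for cas in sorted(_duplicate_cas(ds)):
        violations.append(f"duplicate CAS RN: {cas}")
    return violations


# ---------------------------------------------------------------------------
# design matrices


def build_design_matrices(
    ds: DNTDataset, assignment: PredictorAssignment | None = None
) -> DesignMatrices:
    """Assemble standardized per-key-event predictor blocks X with masks.

    Continuous columns are z-scored over observed entries using the sample
    (n-1) standard deviation; EC columns are log10-transformed first; binary
    columns stay 0/1; the intercept column is constant 1 and never
    standardized.  Missing cells get a 0.0 placeholder and mask 1 — this
    function never imputes.
    """
    violations = validate_dataset(ds)
    if violations:
        raise DatasetValidationError("; ".join(violations))
    assignment = assignment or PredictorAssignment()
    n = len(ds)
    standardization: dict[str, tuple[float, float]] = {}
    col_cache: dict[str, np.ndarray] = {}

    def transformed(col: str) -> np.ndarray:
        if col in col_cache:
            return col_cache[col]
        vals = ds.column(col)
        if col in LOG10_COLUMNS:
            vals = np.where(np.isnan(vals), np.nan, np.log10(vals))
        obs = vals[~np.isnan(vals)]
        if obs.size == 0:
            raise DatasetValidationError(
                f"column '{col}' entirely missing: cannot standardize"
            )
        if col in CONTINUOUS_COLUMNS:
            loc = float(np.mean(obs))
            scale = float(np.std(obs, ddof=1)) if obs.size > 1 else 0.0
            if scale == 0.0:
                raise DatasetValidationError(
                    f"zero-variance continuous column '{col}': cannot standardize"
                )
            vals = (vals - loc) / scale
            standardization[col] = (loc, scale)
        else:  # binary kept 0/1
            standardization[col] = (0.0, 1.0)
        col_cache[col] = vals
        return vals

    xs, misses = {}, {}
    blocks = assignment.blocks()
    for node, cols in blocks.items():
        x = np.zeros((n, len(cols)))
        miss = np.zeros((n, len(cols)), dtype=np.int8)
        for j, col in enumerate(cols):
            if col == "intercept":
                x[:, j] = 1.0
                continue
            vals = transformed(col)
            m = np.isnan(vals)
            x[:, j] = np.where(m, 0.0, vals)
            miss[:, j] = m.astype(np.int8)
        xs[node] = x
        misses[node] = miss

    def y_pair(col: str) -> tuple[np.ndarray, np.ndarray]:
        vals = ds.column(col)
        m = np.isnan(vals)
        return np.where(m, 0, vals).astype(np.int8), m.astype(np.int8)

    y_bdnf, ym_bdnf = y_pair("bdnf_label")
    y_syn, ym_syn = y_pair("syn_label")
    y_nnf, ym_nnf = y_pair("nnf_label")
    y_dnt, ym_dnt = y_pair("dnt_label")
    assert not ym_dnt.any(), "dnt_label must be fully observed"

    return DesignMatrices(
        x_bdnf=xs["bdnf"],
        x_syn=xs["syn"],
        x_nnf=xs["nnf"],
        miss_bdnf=misses["bdnf"],
        miss_syn=misses["syn"],
        miss_nnf=misses["nnf"],
        y_bdnf=y_bdnf,
        y_syn=y_syn,
        y_nnf=y_nnf,
        y_dnt=y_dnt,
        ymiss_bdnf=ym_bdnf,
        ymiss_syn=ym_syn,
        ymiss_nnf=ym_nnf,
        columns=blocks,
        standardization=standardization,
        compound_names=tuple(r.name for r in ds.records),
    )


def empty_design_matrices(block_dims: tuple[int, int, int] = (7, 3, 4)) -> DesignMatrices:
    """Zero-compound design matrices with the given block dimensions.

    Useful for prior-predictive checks: fitting the model to no data must
    reproduce the priors.
    """
    p1, p2, p3 = block_dims
    z = lambda p: np.zeros((0, p))
    zi = lambda p: np.zeros((0, p), dtype=np.int8)
    v = np.zeros(0, dtype=np.int8)
    return DesignMatrices(
        x_bdnf=z(p1),
        x_syn=z(p2),
        x_nnf=z(p3),
        miss_bdnf=zi(p1),
        miss_syn=zi(p2),
        miss_nnf=zi(p3),
        y_bdnf=v,
        y_syn=v.copy(),
        y_nnf=v.copy(),
        y_dnt=v.copy(),
        ymiss_bdnf=v.copy(),
        ymiss_syn=v.copy(),
        ymiss_nnf=v.copy(),
        columns={
            "bdnf": tuple(f"x{j}" for j in range(p1)),
            "syn": tuple(f"x{j}" for j in range(p2)),
            "nnf": tuple(f"x{j}" for j in range(p3)),
        },
        standardization={},
        compound_names=(),
    )


def destandardize(dm: DesignMatrices, col: str, z: np.ndarray) -> np.ndarray:
    """Invert z-scoring (and log10 for EC columns) for a transformed column."""
    loc, scale = dm.standardization[col]
    raw = z * scale + loc
    if col in LOG10_COLUMNS:
        raw = 10.0**raw
    return raw


# ---------------------------------------------------------------------------
# exploratory data analysis


def explore_dataset(ds: DNTDataset, n_bins: int = 10) -> EdaReport:
    """Summarize variable types, distributions, correlations and missingness.

    Pearson correlations are computed on pairwise-complete observations; a
    pair with fewer than two complete cases is reported as NaN (undefined),
    never as 0.
    """
    if len(ds) < 2:
        raise DatasetValidationError("EDA requires at least 2 records")
    numeric_cols = [c for c in COLUMNS if c not in TEXT_COLUMNS]
    df = pd.DataFrame({c: ds.column(c) for c in numeric_cols})

    variable_types = {
        c: ("binary" if c in BINARY_COLUMNS else "continuous") for c in numeric_cols
    }
    histograms = {}
    for c in CONTINUOUS_COLUMNS:
        obs = df[c].dropna().to_numpy()
        if obs.size:
            counts, edges = np.histogram(obs, bins=n_bins)
            histograms[c] = (edges, counts)
    corr = df.corr(method="pearson", min_periods=2)
    missing_fraction = {c: float(df[c].isna().mean()) for c in numeric_cols}
    class_balance = {}
    for c in ("dnt_label", "bdnf_label", "syn_label", "nnf_label"):
        obs = df[c].dropna()
        class_balance[c] = float(obs.mean()) if len(obs) else float("nan")
    return EdaReport(
        variable_types=variable_types,
        histograms=histograms,
        pearson_correlations=corr,
        missing_fraction=missing_fraction,
        class_balance=class_balance,
    )
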