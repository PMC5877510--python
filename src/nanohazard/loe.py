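"""Line-of-evidence (LOE) data model and tabular I/O.

A *line of evidence* is one experimental result extracted from a study:
the nanomaterial it concerns, its physico-chemical characterisation, a
likelihood assignment over five toxicity classes, regulatory study-quality
criteria, and (for network training data) the hazard state observed in the
study. Evidence tables are plain delimited text with a header; missing
values are written as ``-`` and accepted as ``-``, empty, or ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "-"
_MISSING_INPUT = {"-", "", "na", "nan", "none?"}

ADMIN_ROUTES = ("oral", "inhalation", "injection", "intravenous")
STUDY_TYPES = ("in vitro", "in vivo")
HAZARD_STATES = ("None", "Low", "Medium", "High")

QUALITY_CRITERIA = (
    "adequacy",
    "reliability",
    "statistical_power",
    "toxicological_significance",
)

#: physico-chemical criteria accepted without an explicit schema declaration
DEFAULT_PHYSCHEM_CRITERIA = (
    "bet_surface_area",      # m2/g
    "primary_particle_size", # nm
    "aspect_ratio",          # dimensionless, larger:smaller
    "surface_coating",
    "zeta_potential",        # mV
    "purity",
    "composition",
    "bioaccumulation",
    "dissolution",           # %
    "aggregation",
    "shape",
    "surface_reactivity",
)

#: derived WoE columns in their canonical (report) order
PRECOMPUTED_COLUMNS = (
    "s_pchem",
    "s_tox",
    "s_total",
    "quality_weight",
    "weight_norm",
    "weighted_index",
)


class EvidenceError(ValueError):
    """Malformed or invariant-violating evidence data."""


def _is_missing(raw: object) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and math.isnan(raw):
        return True
    return isinstance(raw, str) and raw.strip().lower() in {"-", "", "na", "nan"}


def parse_interval(text: str) -> tuple[float, float]:
    """Parse a discretised numeric state such as ``10-50`` or ``>100``.

    Intervals are half-open ``[low, high)``; ``>x`` maps to ``[x, inf)`` and
    ``<x`` / ``0-x`` to ``[0, x)``. En-dash and hyphen both accepted.
    """
    t = text.strip().replace("–", "-").rstrip("%")
    if t.startswith(">"):
        return (float(t[1:]), math.inf)
    if t.startswith("<"):
        return (0.0, float(t[1:]))
    lo, sep, hi = t.partition("-")
    if not sep:
        raise EvidenceError(f"not an interval: {text!r}")
    return (float(lo), float(hi))


@dataclass(frozen=True)
class ToxClassAssignment:
    """Likelihoods D1..D5 that a study's conclusions fall in toxicity
    classes C1..C5; proportions summing to one."""

    d: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.d) != 5:
            raise EvidenceError("toxicity assignment needs 5 class likelihoods")
        arr = np.asarray(self.d, dtype=float)
        if (arr < 0).any() or (arr > 1).any():
            raise EvidenceError(f"class likelihoods outside [0,1]: {self.d}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise EvidenceError(
                f"class likelihoods sum to {arr.sum():.6g}, expected 1"
            )

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.d, dtype=float)


@dataclass(frozen=True)
class StudyQuality:
    """Regulatory data-quality criteria for one study, each scored in [0,1].

    ``weight_override`` carries a pre-established study weight W_j; when
    present it takes precedence over any combination of the criteria.
    """

    criteria: Mapping[str, float] = field(default_factory=dict)
    weight_override: float | None = None

    def __post_init__(self) -> None:
        for name, score in self.criteria.items():
            if name not in QUALITY_CRITERIA:
                raise EvidenceError(f"unknown quality criterion {name!r}")
            if not 0.0 <= score <= 1.0:
                raise EvidenceError(f"quality score {name}={score} outside [0,1]")
        if self.weight_override is not None and not 0.0 <= self.weight_override <= 1.0:
            raise EvidenceError(
                f"weight override {self.weight_override} outside [0,1]"
            )
        object.__setattr__(self, "criteria", dict(self.criteria))

    def __eq__(self, other) -> bool:  # mapping identity, not object identity
        if not isinstance(other, StudyQuality):
            return NotImplemented
        return (
            dict(self.criteria) == dict(other.criteria)
            and self.weight_override == other.weight_override
        )


@dataclass
class LOERecord:
    """One line of evidence."""

    loe_id: str
    nm: str
    reference: str = ""
    physchem: dict[str, object] = field(default_factory=dict)
    tox: ToxClassAssignment | None = None
    quality: StudyQuality | None = None
    admin_route: str = MISSING
    study_type: str = MISSING
    hazard_label: str = MISSING
    precomputed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not str(self.nm).strip():
            raise EvidenceError(f"LOE {self.loe_id}: empty nanomaterial label")
        if self.admin_route not in ADMIN_ROUTES + (MISSING,):
            raise EvidenceError(
                f"LOE {self.loe_id}: administration route {self.admin_route!r} "
                f"not in {ADMIN_ROUTES}"
            )
        if self.study_type not in STUDY_TYPES + (MISSING,):
            raise EvidenceError(
                f"LOE {self.loe_id}: study type {self.study_type!r} not in {STUDY_TYPES}"
            )
        if self.hazard_label not in HAZARD_STATES + (MISSING,):
            raise EvidenceError(
                f"LOE {self.loe_id}: hazard label {self.hazard_label!r} "
                f"not in {HAZARD_STATES}"
            )
        for col in self.precomputed:
            if col not in PRECOMPUTED_COLUMNS:
                raise EvidenceError(f"LOE {self.loe_id}: unknown derived column {col!r}")
        # canonical form: a pre-established study weight lives in both the
        # quality override and the derived column
        if self.quality is not None and self.quality.weight_override is not None:
            self.precomputed.setdefault("quality_weight", self.quality.weight_override)


@dataclass
class EvidenceTable:
    """Ordered collection of LOE records for a single nanomaterial."""

    nm: str
    records: list[LOERecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.loe_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise EvidenceError(f"duplicate loe_id values: {dupes}")
        for r in self.records:
            if r.nm != self.nm:
                raise EvidenceError(
                    f"LOE {r.loe_id}: nanomaterial {r.nm!r} does not match "
                    f"table label {self.nm!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def has_precomputed(self) -> bool:
        return bool(self.records) and all(
            {"s_pchem", "s_tox", "quality_weight"} <= set(r.precomputed)
            for r in self.records
        )

    def column(self, name: str) -> np.ndarray:
        """Vector of one derived column across records (NaN where absent)."""
        return np.array(
            [r.precomputed.get(name, math.nan) for r in self.records], dtype=float
        )


# ---------------------------------------------------------------------------
# tabular I/O

def _norm_cat(raw: object, vocabulary: Sequence[str], *, row: object, col: str) -> str:
    if _is_missing(raw):
        return MISSING
    text = str(raw).strip()
    for state in vocabulary:
        if text.lower() == state.lower():
            return state
    raise EvidenceError(f"row {row}, column {col!r}: undeclared state {text!r}")


def _parse_cell(raw: str) -> object:
    """Numbers become floats; anything else stays a (categorical) string."""
    try:
        return float(raw)
    except (TypeError, ValueError):
        return str(raw).strip()


def read_evidence_table(
    path: str | Path,
    schema: Mapping | None = None,
) -> EvidenceTable:
    """Read a delimited evidence table.

    ``schema`` may declare ``column_map`` (file header -> canonical name),
    ``physchem_criteria`` (criteria accepted beyond the built-in list),
    ``delimiter``, and ``nm`` (table label when the file has no nm column).
    """
    schema = dict(schema or {})
    delimiter = schema.get("delimiter")
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            dtype=str,
            keep_default_na=False,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise EvidenceError(f"{path}: malformed table: {exc}") from exc

    colmap = {str(k): str(v) for k, v in schema.get("column_map", {}).items()}
    df = df.rename(columns=colmap)
    known_pc = set(DEFAULT_PHYSCHEM_CRITERIA) | set(schema.get("physchem_criteria", ()))

    records: list[LOERecord] = []
    nm_label = schema.get("nm")
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        try:
            records.append(_row_to_record(row, df.columns, known_pc, rownum, nm_label))
        except EvidenceError:
            raise
        except (ValueError, KeyError) as exc:
            raise EvidenceError(f"{path}: row {rownum}: {exc}") from exc
    if nm_label is None:
        nms = {r.nm for r in records}
        if len(nms) > 1:
            raise EvidenceError(
                f"{path}: multiple nanomaterials {sorted(nms)}; split tables per NM "
                "or pass schema['nm']"
            )
        nm_label = nms.pop() if nms else "unknown"
    return EvidenceTable(nm=str(nm_label), records=records)


def _row_to_record(row, columns, known_pc, rownum, nm_fallback=None) -> LOERecord:
    get = lambda c: row[c] if c in columns else None

    d_cols = [f"d{i}" for i in range(1, 6)]
    tox = None
    if all(c in columns for c in d_cols) and not all(_is_missing(get(c)) for c in d_cols):
        try:
            tox = ToxClassAssignment(tuple(float(get(c)) for c in d_cols))
        except EvidenceError as exc:
            raise EvidenceError(f"row {rownum}, columns d1..d5: {exc}") from exc

    crit = {
        name: float(get(f"q_{name}"))
        for name in QUALITY_CRITERIA
        if f"q_{name}" in columns and not _is_missing(get(f"q_{name}"))
    }
    override_col = "quality_weight"
    override = (
        float(get(override_col))
        if override_col in columns and not _is_missing(get(override_col))
        else None
    )
    quality = StudyQuality(crit, override) if (crit or override is not None) else None

    physchem: dict[str, object] = {}
    for col in columns:
        if not col.startswith("pc_"):
            continue
        name = col[3:]
        if name not in known_pc:
            raise EvidenceError(
                f"row {rownum}, column {col!r}: undeclared physico-chemical "
                f"criterion {name!r}"
            )
        if not _is_missing(row[col]):
            physchem[name] = _parse_cell(row[col])

    precomputed = {
        c: float(get(c))
        for c in PRECOMPUTED_COLUMNS
        if c in columns and not _is_missing(get(c))
    }
    if override is not None:
        precomputed["quality_weight"] = override

    return LOERecord(
        loe_id=str(get("loe_id") if "loe_id" in columns else rownum - 1),
        nm=(
            str(get("nm"))
            if "nm" in columns and not _is_missing(get("nm"))
            else str(nm_fallback or "")
        ),
        reference=str(get("reference")) if "reference" in columns and not _is_missing(get("reference")) else "",
        physchem=physchem,
        tox=tox,
        quality=quality,
        admin_route=_norm_cat(get("admin_route"), ADMIN_ROUTES, row=rownum, col="admin_route"),
        study_type=_norm_cat(get("study_type"), STUDY_TYPES, row=rownum, col="study_type"),
        hazard_label=_norm_cat(get("hazard_label"), HAZARD_STATES, row=rownum, col="hazard_label"),
        precomputed=precomputed,
    )


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_evidence_table(table: EvidenceTable, path: str | Path) -> None:
    """Write a table so that :func:`read_evidence_table` round-trips it."""
    pc_names = sorted({name for r in table.records for name in r.physchem})
    has_tox = any(r.tox is not None for r in table.records)
    q_names = sorted(
        {n for r in table.records if r.quality for n in r.quality.criteria}
    )
    has_override = any(
        r.quality and r.quality.weight_override is not None for r in table.records
    )
    pre_names = [
        c
        for c in PRECOMPUTED_COLUMNS
        if any(c in r.precomputed for r in table.records)
        or (c == "quality_weight" and has_override)
    ]

    header = ["loe_id", "reference", "nm", "admin_route", "study_type", "hazard_label"]
    header += [f"pc_{n}" for n in pc_names]
    header += [f"d{i}" for i in range(1, 6)] if has_tox else []
    header += [f"q_{n}" for n in q_names]
    header += pre_names

    rows = []
    for r in table.records:
        row = {
            "loe_id": r.loe_id,
            "reference": r.reference or MISSING,
            "nm": r.nm,
            "admin_route": r.admin_route,
            "study_type": r.study_type,
            "hazard_label": r.hazard_label,
        }
        for n in pc_names:
            row[f"pc_{n}"] = _fmt(r.physchem[n]) if n in r.physchem else MISSING
        if has_tox:
            for i in range(1, 6):
                row[f"d{i}"] = repr(r.tox.d[i - 1]) if r.tox else MISSING
        for n in q_names:
            row[f"q_{n}"] = (
                repr(r.quality.criteria[n])
                if r.quality and n in r.quality.criteria
                else MISSING
            )
        for c in pre_names:
            row[c] = _fmt(r.precomputed[c]) if c in r.precomputed else MISSING
        if r.quality and r.quality.weight_override is not None:
            row["quality_weight"] = repr(r.quality.weight_override)
        rows.append(row)

    out = pd.DataFrame(rows, columns=header)
    try:
        out.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write evidence table to {path}: {exc}") from exc


def tio2_fixture() -> EvidenceTable:
    """The bundled 22-LOE nano-TiO2 weight-of-evidence table.

    Carries the published per-study physico-chemical index, toxicity index,
    aggregated index, and study-quality weight at printed (2-decimal)
    precision. Raw physico-chemical measurements were not published, so the
    fixture holds the aggregated indices only.
    """
    ref = resources.files("nanohazard.data").joinpath("tio2_woe_table.csv")
    with resources.as_file(ref) as path:
        return read_evidence_table(path)
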