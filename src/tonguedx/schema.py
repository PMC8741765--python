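"""Tongue-feature vocabulary and its numeric encoding.

A cohort record holds eight clinically scored tongue features used in
Traditional Chinese Medicine screening for diabetes mellitus (Xiao-Ke):
tongue body shape, tongue colour, four surface marks (multi-label),
teeth markings, fur colour, saliva state and fur thickness, plus an
optional DM / non_DM label.

The classifier consumes a length-8 numeric vector.  Two documented
encoding schemes are provided, both mapping every category to a code in
[0, 1]:

``ordinal``
    Categories coded in vocabulary (listing) order, uniformly spaced in
    [0, 1].  The four non-fissure surface marks are pooled into a single
    spot score ``(red_spots + black_spots + petechiae) / 3``; fissures
    and teeth markings are 0/1 flags.

``severity-scaled``
    Same geometry, but categories ordered by their conventional
    association with diabetes (e.g. bluish tongue, yellow fur and thick
    fur code highest).

Vector layout (fixed): ``[tongue_color, tongue_body, fur_color,
fur_thickness, spot_score, saliva, fissures, teeth_markings]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

DM = "DM"
NON_DM = "non_DM"
LABELS = (NON_DM, DM)

# single-valued feature vocabularies, in listing order
TONGUE_BODY = ("medium", "enlarged", "small")
TONGUE_COLOR = ("mild_red", "red", "pale", "bluish")
FUR_COLOR = ("white", "black", "yellow", "none")
SALIVA = ("normal", "dry", "wet")
FUR_THICKNESS = ("thin", "thick", "no_fur")
SURFACE_MARKS = ("red_spots", "black_spots", "fissures", "petechiae")

CATEGORICAL_FEATURES = {
    "tongue_body": TONGUE_BODY,
    "tongue_color": TONGUE_COLOR,
    "fur_color": FUR_COLOR,
    "saliva": SALIVA,
    "fur_thickness": FUR_THICKNESS,
}

#: feature-table column order (External Interfaces contract)
COLUMNS = (
    "tongue_body",
    "tongue_color",
    "red_spots",
    "black_spots",
    "fissures",
    "petechiae",
    "teeth_markings",
    "fur_color",
    "saliva",
    "fur_thickness",
)
OPTIONAL_COLUMNS = ("label", "phase")

FEATURE_NAMES = (
    "tongue_color",
    "tongue_body",
    "fur_color",
    "fur_thickness",
    "spot_score",
    "saliva",
    "fissures",
    "teeth_markings",
)

ENCODING_SCHEMES = ("ordinal", "severity-scaled")

# severity orders: category position reflects conventional association with DM
_SEVERITY_ORDER = {
    "tongue_color": ("mild_red", "pale", "red", "bluish"),
    "tongue_body": ("medium", "small", "enlarged"),
    "fur_color": ("white", "none", "black", "yellow"),
    "fur_thickness": ("no_fur", "thin", "thick"),
    "saliva": ("normal", "wet", "dry"),
}


def _codes(order: Sequence[str]) -> dict[str, float]:
    n = len(order)
    return {cat: i / (n - 1) for i, cat in enumerate(order)}


def code_table(scheme: str = "ordinal") -> dict[str, dict[str, float]]:
    """Numeric code assigned to every category of every single-valued feature.

    The returned mapping is the documented encoding contract: tests and the
    decoder both read it rather than re-deriving codes.
    """
    if scheme == "ordinal":
        orders = {k: v for k, v in CATEGORICAL_FEATURES.items()}
    elif scheme == "severity-scaled":
        orders = _SEVERITY_ORDER
    else:
        raise SchemaError(f"unknown encoding scheme: {scheme!r}")
    return {feat: _codes(order) for feat, order in orders.items()}


@dataclass(frozen=True)
class TongueRecord:
    """One participant's scored tongue features and optional DM label."""

    tongue_body: str
    tongue_color: str
    red_spots: bool
    black_spots: bool
    fissures: bool
    petechiae: bool
    teeth_markings: bool
    fur_color: str
    saliva: str
    fur_thickness: str
    label: Optional[str] = None
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        for feat, vocab in CATEGORICAL_FEATURES.items():
            val = getattr(self, feat)
            if val not in vocab:
                raise SchemaError(f"unknown {feat} value: {val!r}")
        if self.label is not None and self.label not in LABELS:
            raise SchemaError(f"unknown label value: {self.label!r}")

    def surface_marks(self) -> frozenset[str]:
        return frozenset(m for m in SURFACE_MARKS if getattr(self, m))


@dataclass(frozen=True)
class FeatureVector:
    """Numeric encoding of a record; ``values`` has the configured input
    dimension (8 for the native tongue features)."""

    values: tuple[float, ...]
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.values):
            raise SchemaError("feature vector contains non-finite entries")


def encode_record(record: TongueRecord, scheme: str = "ordinal") -> FeatureVector:
    """Encode one record into the fixed 8-dimensional input layout.

    Deterministic and invertible (via :func:`decode_vector`) for all
    single-valued features; the pooled spot score only preserves the
    number of non-fissure surface marks.
    """
    codes = code_table(scheme)
    spot_score = (record.red_spots + record.black_spots + record.petechiae) / 3.0
    values = (
        codes["tongue_color"][record.tongue_color],
        codes["tongue_body"][record.tongue_body],
        codes["fur_color"][record.fur_color],
        codes["fur_thickness"][record.fur_thickness],
        spot_score,
        codes["saliva"][record.saliva],
        float(record.fissures),
        float(record.teeth_markings),
    )
    return FeatureVector(values=values, label=record.label)


def decode_vector(vec: FeatureVector, scheme: str = "ordinal") -> dict[str, object]:
    """Invert the documented encoding for the single-valued features.

    Returns a dict of recovered categories plus the spot count and the two
    flags; raises :class:`SchemaError` if a coordinate is not a legal code.
    """
    codes = code_table(scheme)
    out: dict[str, object] = {}
    slots = ("tongue_color", "tongue_body", "fur_color", "fur_thickness")
    for i, feat in enumerate(slots):
        inv = {v: k for k, v in codes[feat].items()}
        match = [cat for v, cat in inv.items() if abs(v - vec.values[i]) < 1e-9]
        if not match:
            raise SchemaError(f"{feat}: {vec.values[i]} is not a documented code")
        out[feat] = match[0]
    inv_sal = {v: k for k, v in codes["saliva"].items()}
    match = [cat for v, cat in inv_sal.items() if abs(v - vec.values[5]) < 1e-9]
    if not match:
        raise SchemaError(f"saliva: {vec.values[5]} is not a documented code")
    out["saliva"] = match[0]
    out["spot_count"] = int(round(vec.values[4] * 3))
    out["fissures"] = bool(round(vec.values[6]))
    out["teeth_markings"] = bool(round(vec.values[7]))
    return out


def encode_records(
    records: Sequence[TongueRecord], scheme: str = "ordinal"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised encoding: returns (X, y) with X shape (n, 8) and y an
    object array of labels (None entries allowed only for unlabeled use)."""
    vecs = [encode_record(r, scheme) for r in records]
    X = np.array([v.values for v in vecs], dtype=float)
    y = np.array([v.label for v in vecs], dtype=object)
    return X, y


# ---------------------------------------------------------------------------
# feature-table I/O


def _parse_bool(cell: object, row: int, col: str) -> bool:
    s = str(cell).strip()
    if s in ("0", "1"):
        return s == "1"
    raise SchemaError(f"row {row}, column {col!r}: expected 0/1, got {cell!r}")


def read_feature_table(path, dialect: str = "comma") -> list[TongueRecord]:
    """Parse a delimited feature table into records.

    ``dialect`` is ``comma`` (default) or ``tab``.  Boolean columns use
    0/1.  Errors name the offending 1-based data row and column.
    """
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    records = []
    has_label = "label" in df.columns
    has_phase = "phase" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        try:
            rec = TongueRecord(
                tongue_body=d["tongue_body"],
                tongue_color=d["tongue_color"],
                red_spots=_parse_bool(d["red_spots"], i, "red_spots"),
                black_spots=_parse_bool(d["black_spots"], i, "black_spots"),
                fissures=_parse_bool(d["fissures"], i, "fissures"),
                petechiae=_parse_bool(d["petechiae"], i, "petechiae"),
                teeth_markings=_parse_bool(d["teeth_markings"], i, "teeth_markings"),
                fur_color=d["fur_color"],
                saliva=d["saliva"],
                fur_thickness=d["fur_thickness"],
                label=(d["label"] or None) if has_label else None,
                phase=(d["phase"] or None) if has_phase else None,
            )
        except SchemaError as e:
            raise SchemaError(f"row {i}: {e}") from None
        records.append(rec)
    return records


def write_feature_table(records: Iterable[TongueRecord], path, dialect: str = "comma") -> None:
    """Write records in the canonical column order; inverse of
    :func:`read_feature_table` (byte-identical round trip)."""
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect: {dialect!r}")
    records = list(records)
    cols = list(COLUMNS)
    if any(r.label is not None for r in records):
        cols.append("label")
    if any(r.phase is not None for r in records):
        cols.append("phase")
    rows = []
    for r in records:
        d = {
            "tongue_body": r.tongue_body,
            "tongue_color": r.tongue_color,
            "red_spots": int(r.red_spots),
            "black_spots": int(r.black_spots),
            "fissures": int(r.fissures),
            "petechiae": int(r.petechiae),
            "teeth_markings": int(r.teeth_markings),
            "fur_color": r.fur_color,
            "saliva": r.saliva,
            "fur_thickness": r.fur_thickness,
        }
        if "label" in cols:
            d["label"] = r.label if r.label is not None else ""
        if "phase" in cols:
            d["phase"] = r.phase if r.phase is not None else ""
        rows.append(d)
    df = pd.DataFrame(rows, columns=cols)
    buf = io.StringIO()
    df.to_csv(buf, sep=sep, index=False, lineterminator="\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)


def with_label(record: TongueRecord, label: Optional[str]) -> TongueRecord:
    return replace(record, label=label)
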