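"""Typed tabular data model, CSV/ARFF I/O, and information-theoretic primitives.

The toolkit operates on rectangular patient-record tables with one binary
class attribute (1 = event, e.g. an exacerbation; 0 = no event) and a mix of
continuous and discrete predictors.  All entropies are reported in bits
(logarithms base 2), the convention of the MDL / information-gain literature
this package builds on.
"""
from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "DataTable",
    "CountVector",
    "HcesError",
    "MissingClassError",
    "ClassArityError",
    "RaggedRowError",
    "MissingValueError",
    "UnreadableFileError",
    "ConfigError",
    "entropy",
    "symmetrical_uncertainty",
    "read_table",
    "write_table",
    "get_logger",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class HcesError(Exception):
    """Base class for all package errors."""


class MissingClassError(HcesError):
    """The designated class column is absent from the input."""


class ClassArityError(HcesError):
    """The class column does not have exactly two observed values."""


class RaggedRowError(HcesError):
    """A data row does not provide one value per declared attribute."""


class MissingValueError(HcesError):
    """A missing value was encountered and missing values are not allowed."""


class UnreadableFileError(HcesError):
    """The input file could not be parsed in the requested format."""


class ConfigError(HcesError):
    """Invalid configuration value."""


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------

_LOG_FORMAT = "%(asctime)s %(levelname)s [%(name)s] %(message)s"


def get_logger(stage: str) -> logging.Logger:
    """Return a stage-tagged logger (``hces.<stage>``) with timestamped output."""
    root = logging.getLogger("hces")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logging.getLogger(f"hces.{stage}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

CONTINUOUS = "continuous"
DISCRETE = "discrete"
PREDICTOR = "predictor"
CLASS = "class"


@dataclass(frozen=True)
class AttributeSpec:
    """Declaration of one table column: its name, kind, role and state set."""

    name: str
    kind: str  # continuous | discrete
    role: str = PREDICTOR  # predictor | class
    states: tuple[str, ...] | None = None  # discrete only, ordered

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, DISCRETE):
            raise ConfigError(f"unknown attribute kind {self.kind!r}")
        if self.role not in (PREDICTOR, CLASS):
            raise ConfigError(f"unknown attribute role {self.role!r}")
        if self.kind == DISCRETE:
            if self.states is None or len(self.states) == 0:
                raise ConfigError(f"discrete attribute {self.name!r} needs states")
            if len(set(self.states)) != len(self.states):
                raise ConfigError(f"duplicate states in attribute {self.name!r}")
        elif self.states is not None:
            raise ConfigError(f"continuous attribute {self.name!r} cannot have states")
        if self.role == CLASS:
            if self.kind != DISCRETE or len(self.states or ()) != 2:
                raise ClassArityError(
                    f"class attribute {self.name!r} must be discrete with exactly 2 states"
                )


@dataclass(frozen=True)
class CountVector:
    """Nonnegative per-class-state counts; the input shape of `entropy`."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def __add__(self, other: "CountVector") -> "CountVector":
        return CountVector(tuple(a + b for a, b in zip(self.counts, other.counts)))


class DataTable:
    """Labelled rectangular records with typed attribute specs.

    Wraps a :class:`pandas.DataFrame` whose columns match ``specs`` in order.
    Discrete columns hold state labels (strings); continuous columns hold
    floats.  Exactly one spec has role ``class``; it is discrete with two
    states, canonically ``("0", "1")`` with ``"1"`` the positive event.
    """

    def __init__(self, frame: pd.DataFrame, specs: Sequence[AttributeSpec],
                 allow_missing: bool = False):
        specs = list(specs)
        if list(frame.columns) != [s.name for s in specs]:
            raise RaggedRowError("frame columns do not match attribute specs")
        class_specs = [s for s in specs if s.role == CLASS]
        if len(class_specs) != 1:
            raise MissingClassError(
                f"exactly one class attribute required, found {len(class_specs)}"
            )
        self._frame = frame.reset_index(drop=True)
        self._specs = specs
        self._by_name = {s.name: s for s in specs}
        if len(self._by_name) != len(specs):
            raise ConfigError("duplicate attribute names")
        self.allow_missing = allow_missing
        self._code_cache: dict[str, np.ndarray] = {}
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        for s in self._specs:
            col = self._frame[s.name]
            if col.isna().any():
                if not self.allow_missing or s.role == CLASS:
                    raise MissingValueError(f"missing values in attribute {s.name!r}")
            if s.kind == DISCRETE:
                observed = set(col.dropna().astype(str))
                extra = observed - set(s.states or ())
                if extra:
                    raise ConfigError(
                        f"attribute {s.name!r} has values outside declared states: {sorted(extra)}"
                    )

    # -- basic accessors -----------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def specs(self) -> list[AttributeSpec]:
        return list(self._specs)

    @property
    def n(self) -> int:
        return len(self._frame)

    @property
    def class_name(self) -> str:
        return next(s.name for s in self._specs if s.role == CLASS)

    @property
    def predictor_names(self) -> list[str]:
        return [s.name for s in self._specs if s.role == PREDICTOR]

    def spec(self, name: str) -> AttributeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no attribute named {name!r}") from None

    def states(self, name: str) -> tuple[str, ...]:
        s = self.spec(name)
        if s.kind != DISCRETE:
            raise ConfigError(f"attribute {name!r} is continuous, has no states")
        return s.states  # type: ignore[return-value]

    def values(self, name: str) -> np.ndarray:
        """Raw column values (floats for continuous, labels for discrete)."""
        col = self._frame[self.spec(name).name]
        if self.spec(name).kind == CONTINUOUS:
            return col.to_numpy(dtype=float)
        return col.to_numpy()

    def codes(self, name: str) -> np.ndarray:
        """Integer state codes for a discrete column (-1 marks missing)."""
        if name not in self._code_cache:
            s = self.spec(name)
            if s.kind != DISCRETE:
                raise ConfigError(f"attribute {name!r} is continuous, has no codes")
            lut = {v: i for i, v in enumerate(s.states or ())}
            col = self._frame[name]
            codes = np.array(
                [-1 if pd.isna(v) else lut[str(v)] for v in col], dtype=np.int64
            )
            self._code_cache[name] = codes
        return self._code_cache[name]

    def class_codes(self) -> np.ndarray:
        return self.codes(self.class_name)

    # -- derived tables ------------------------------------------------------

    def project(self, predictors: Iterable[str]) -> "DataTable":
        """Restrict to a predictor subset (the class column is always kept)."""
        keep = [p for p in predictors]
        unknown = set(keep) - set(self.predictor_names)
        if unknown:
            raise KeyError(f"unknown predictors {sorted(unknown)}")
        order = [s.name for s in self._specs if s.name in keep or s.role == CLASS]
        specs = [self._by_name[c] for c in order]
        return DataTable(self._frame[order].copy(), specs, self.allow_missing)

    def subset_rows(self, index: np.ndarray) -> "DataTable":
        return DataTable(self._frame.iloc[index].reset_index(drop=True),
                         self._specs, self.allow_missing)

    def with_column(self, spec: AttributeSpec, values: Sequence) -> "DataTable":
        """Return a copy where column ``spec.name`` is replaced."""
        frame = self._frame.copy()
        frame[spec.name] = list(values)
        specs = [spec if s.name == spec.name else s for s in self._specs]
        return DataTable(frame, specs, self.allow_missing)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"DataTable(n={self.n}, predictors={len(self.predictor_names)}, "
                f"class={self.class_name!r})")


# ---------------------------------------------------------------------------
# Information-theoretic primitives
# ---------------------------------------------------------------------------

def entropy(counts) -> float:
    """Shannon entropy in bits of a count vector, with 0·log 0 = 0.

    Accepts a :class:`CountVector` or any sequence of nonnegative numbers.
    An all-zero (or empty) vector has entropy 0 by convention.
    """
    if isinstance(counts, CountVector):
        counts = counts.counts
    a = np.asarray(counts, dtype=float)
    if a.size and (a < 0).any():
        raise ValueError("negative counts")
    total = a.sum()
    if total == 0:
        return 0.0
    p = a[a > 0] / total
    return float(-(p * np.log2(p)).sum())


def _as_codes(column) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(column), sort=True)
    if (codes < 0).any():
        raise MissingValueError("missing values in discrete column")
    return codes.astype(np.int64), max(len(uniques), 1)


def joint_counts(x, y) -> np.ndarray:
    """Contingency table of two discrete columns (codes or raw labels)."""
    xc, kx = _as_codes(x)
    yc, ky = _as_codes(y)
    if len(xc) != len(yc):
        raise ValueError("length mismatch")
    return np.bincount(xc * ky + yc, minlength=kx * ky).reshape(kx, ky)


def symmetrical_uncertainty(x, y) -> float:
    """Symmetrical uncertainty 2·[H(X)+H(Y)−H(X,Y)] / [H(X)+H(Y)] in [0, 1].

    The correlation surrogate used for CFS on discretized data; 0 when both
    columns are constant (H(X)+H(Y) = 0).
    """
    joint = joint_counts(x, y)
    hx = entropy(joint.sum(axis=1))
    hy = entropy(joint.sum(axis=0))
    hxy = entropy(joint.ravel())
    denom = hx + hy
    if denom == 0:
        return 0.0
    su = 2.0 * (hx + hy - hxy) / denom
    # clamp float noise; SU is mathematically in [0, 1]
    return float(min(max(su, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _infer_kind(col: pd.Series) -> str:
    """Numeric non-integer-coded columns are continuous; all else discrete."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.isna().any():
        return DISCRETE
    vals = numeric.to_numpy(dtype=float)
    if np.allclose(vals, np.round(vals)):
        return DISCRETE  # integer-coded category until overridden
    return CONTINUOUS


def _canonical_class_states(observed: list[str]) -> tuple[list[str], dict[str, str]]:
    """Map the two observed class values to canonical states ("0", "1").

    If the observed values already are {0, 1} (as numbers or strings) the
    natural mapping is used; otherwise values are sorted and the larger one
    becomes the positive state "1".
    """
    ordered = sorted(observed, key=lambda v: (len(v), v))
    mapping = {ordered[0]: "0", ordered[1]: "1"}
    return ["0", "1"], mapping


def _build_table(frame: pd.DataFrame, class_name: str,
                 declared: Mapping[str, AttributeSpec] | None = None,
                 overrides: Mapping[str, str] | None = None,
                 allow_missing: bool = False) -> DataTable:
    if class_name not in frame.columns:
        raise MissingClassError(f"class not found: no column named {class_name!r}")
    observed_class = sorted({str(v) for v in frame[class_name].dropna()})
    if len(observed_class) != 2:
        raise ClassArityError(
            f"class column {class_name!r} has {len(observed_class)} values, expected 2"
        )
    _, class_map = _canonical_class_states(observed_class)
    overrides = dict(overrides or {})
    specs: list[AttributeSpec] = []
    out = {}
    for col in frame.columns:
        series = frame[col]
        if col == class_name:
            mapped = series.astype(str).map(class_map)
            specs.append(AttributeSpec(col, DISCRETE, CLASS, ("0", "1")))
            out[col] = mapped
            continue
        if declared and col in declared:
            spec = declared[col]
        else:
            kind = overrides.get(col) or _infer_kind(series.dropna())
            if kind not in (CONTINUOUS, DISCRETE):
                raise ConfigError(f"invalid kind override {kind!r} for {col!r}")
            if kind == DISCRETE:
                states = tuple(sorted({str(v) for v in series.dropna()},
                                      key=_state_sort_key))
                spec = AttributeSpec(col, DISCRETE, PREDICTOR, states)
            else:
                spec = AttributeSpec(col, CONTINUOUS, PREDICTOR)
        if spec.kind == DISCRETE:
            out[col] = series.where(series.isna(), series.astype(str))
        else:
            out[col] = pd.to_numeric(series, errors="raise")
        specs.append(spec)
    return DataTable(pd.DataFrame(out, columns=list(frame.columns)), specs,
                     allow_missing)


def _state_sort_key(v: str):
    try:
        return (0, float(v), v)
    except ValueError:
        return (1, 0.0, v)


def read_table(path, fmt: str | None = None, class_name: str = "Exacer",
               overrides: Mapping[str, str] | None = None,
               allow_missing: bool = False) -> DataTable:
    """Read a CSV or ARFF file into a :class:`DataTable`.

    ``fmt`` defaults from the file suffix.  ``overrides`` maps attribute
    names to ``"continuous"``/``"discrete"`` to correct kind inference
    (integer-coded categories vs. integer-valued measurements).
    """
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"no such file: {path}")
    fmt = fmt or ("arff" if path.suffix.lower() == ".arff" else "csv")
    if fmt == "csv":
        return _read_csv(path, class_name, overrides, allow_missing)
    if fmt == "arff":
        return _read_arff(path, class_name, overrides, allow_missing)
    raise ConfigError(f"unknown table format {fmt!r}")


def _read_csv(path: Path, class_name, overrides, allow_missing) -> DataTable:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise UnreadableFileError(f"empty CSV file: {path}")
    header = rows[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise RaggedRowError(f"line {i}: expected {width} fields, got {len(row)}")
    frame = pd.DataFrame(rows[1:], columns=header)
    frame = frame.replace({"": np.nan, "?": np.nan})
    return _build_table(frame, class_name, None, overrides, allow_missing)


def _read_arff(path: Path, class_name, overrides, allow_missing) -> DataTable:
    """Minimal Weka-dialect ARFF reader (nominal and numeric attributes)."""
    names: list[str] = []
    declared: dict[str, AttributeSpec] = {}
    data_rows: list[list[str]] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if in_data:
                data_rows.append(next(csv.reader(io.StringIO(line))))
            elif low.startswith("@relation"):
                continue
            elif low.startswith("@attribute"):
                rest = line.split(None, 1)[1]
                if "{" in rest:
                    name, spec = rest.split("{", 1)
                    name = name.strip().strip("'\"")
                    states = tuple(s.strip().strip("'\"")
                                   for s in spec.rstrip("}").split(","))
                    names.append(name)
                    if name != class_name:
                        declared[name] = AttributeSpec(name, DISCRETE, PREDICTOR, states)
                else:
                    parts = rest.rsplit(None, 1)
                    if len(parts) != 2 or parts[1].lower() not in ("numeric", "real", "integer"):
                        raise UnreadableFileError(f"unsupported ARFF attribute: {line}")
                    name = parts[0].strip().strip("'\"")
                    names.append(name)
                    if name != class_name:
                        declared[name] = AttributeSpec(name, CONTINUOUS, PREDICTOR)
            elif low.startswith("@data"):
                in_data = True
            else:
                raise UnreadableFileError(f"unrecognized ARFF line: {line}")
    if not in_data or not names:
        raise UnreadableFileError(f"not a valid ARFF file: {path}")
    width = len(names)
    for i, row in enumerate(data_rows, start=1):
        if len(row) != width:
            raise RaggedRowError(f"data row {i}: expected {width} fields, got {len(row)}")
    frame = pd.DataFrame(data_rows, columns=names).replace({"?": np.nan, "": np.nan})
    return _build_table(frame, class_name, declared, overrides, allow_missing)


def write_table(table: DataTable, path, fmt: str | None = None) -> None:
    """Write a :class:`DataTable` as CSV or ARFF (lossless on values/specs)."""
    path = Path(path)
    fmt = fmt or ("arff" if path.suffix.lower() == ".arff" else "csv")
    if fmt == "csv":
        table.frame.to_csv(path, index=False)
        return
    if fmt != "arff":
        raise ConfigError(f"unknown table format {fmt!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@relation hces\n\n")
        for s in table.specs:
            if s.kind == DISCRETE:
                fh.write(f"@attribute {s.name} {{{','.join(s.states or ())}}}\n")
            else:
                fh.write(f"@attribute {s.name} numeric\n")
        fh.write("\n@data\n")
        writer = csv.writer(fh, lineterminator="\n")
        for _, row in table.frame.iterrows():
            writer.writerow(["?" if pd.isna(v) else v for v in row])
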