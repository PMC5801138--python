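"""Descriptor/Calculator framework.

Two classes carry the architecture: :class:`Descriptor`, a named,
parameterised, self-describing calculation unit that returns one scalar per
molecule, and :class:`Calculator`, which holds an ordered registry of
descriptors, resolves shared intermediates through a per-molecule cache,
contains every failure as a typed :class:`MissingValue` (never an exception,
unless strict mode is on), and maps over molecule batches serially or with
process parallelism while preserving input order.

``Calculator`` is also a scikit-learn transformer: ``fit`` freezes the
descriptor list, ``transform`` returns an ``(n_molecules, n_descriptors)``
float matrix with missing values encoded as NaN, and
``get_feature_names_out`` exposes the descriptor names, so it composes with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass
from enum import Enum
from multiprocessing import get_context
from typing import Any, Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import (
    DisconnectedGraphError,
    EmptyGraphError,
    MolecularGraph,
    PreprocessPolicy,
    preprocess,
)

__all__ = [
    "MissingReason",
    "MissingValue",
    "Descriptor",
    "Context",
    "ResultSet",
    "Calculator",
    "TimeBudgetExceeded",
    "UnsupportedAtomError",
]


class MissingReason(str, Enum):
    parse_failure = "parse_failure"
    disconnected = "disconnected"
    empty_graph = "empty_graph"
    divide_by_zero = "divide_by_zero"
    unsupported_atom = "unsupported_atom"
    dependency_failure = "dependency_failure"
    timeout = "timeout"


class TimeBudgetExceeded(RuntimeError):
    """Raised internally when an optional per-molecule work budget runs out."""


class UnsupportedAtomError(ValueError):
    """Raised when an atom falls outside a descriptor's supported elements."""


@dataclass(frozen=True)
class MissingValue:
    """A typed non-result: carries the causal error instead of raising."""

    reason: MissingReason
    message: str = ""
    descriptor: str = ""

    def __float__(self) -> float:
        return float("nan")

    def __repr__(self) -> str:  # compact, log-friendly
        return f"MissingValue({self.reason.value}: {self.descriptor} {self.message})".rstrip()


def is_missing(value: Any) -> bool:
    return isinstance(value, MissingValue)


class Context:
    """Per-molecule evaluation context with a shared-intermediate cache.

    Descriptors request intermediates (distance matrix, delta vectors,
    subgraph enumerations, ...) through :meth:`intermediate`; each is built
    at most once per molecule when caching is enabled. Disabling the cache
    never changes any value, only the work done.
    """

    def __init__(self, mol: MolecularGraph, use_cache: bool = True) -> None:
        self.mol = mol
        self.use_cache = use_cache
        self._intermediates: dict[Any, Any] = {}
        self._values: dict[str, Any] = {}

    def intermediate(self, key: Any, builder: Callable[["Context"], Any]) -> Any:
        if not self.use_cache:
            return builder(self)
        if key not in self._intermediates:
            self._intermediates[key] = builder(self)
        return self._intermediates[key]

    def descriptor_value(self, desc: "Descriptor") -> Any:
        """Evaluate a descriptor through the framework's error containment."""
        name = desc.name
        if self.use_cache and name in self._values:
            return self._values[name]
        value = _evaluate(desc, self)
        if self.use_cache:
            self._values[name] = value
        return value


def _evaluate(desc: "Descriptor", ctx: Context) -> Any:
    """Run one descriptor, translating exceptions to typed missing values."""
    mol = ctx.mol
    if mol.parse_error is not None:
        return MissingValue(MissingReason.parse_failure, mol.parse_error, desc.name)
    try:
        value = desc.compute(mol, ctx)
    except DisconnectedGraphError as exc:
        return MissingValue(MissingReason.disconnected, str(exc), desc.name)
    except EmptyGraphError as exc:
        return MissingValue(MissingReason.empty_graph, str(exc), desc.name)
    except ZeroDivisionError as exc:
        return MissingValue(MissingReason.divide_by_zero, str(exc), desc.name)
    except UnsupportedAtomError as exc:
        return MissingValue(MissingReason.unsupported_atom, str(exc), desc.name)
    except TimeBudgetExceeded as exc:
        return MissingValue(MissingReason.timeout, str(exc), desc.name)
    except Exception as exc:  # containment: nothing escapes calculate()
        return MissingValue(MissingReason.dependency_failure, repr(exc), desc.name)
    if isinstance(value, MissingValue):
        return value
    if isinstance(value, float) and not math.isfinite(value):
        return MissingValue(
            MissingReason.divide_by_zero, "non-finite result", desc.name
        )
    return value


class Descriptor:
    """Base class of every descriptor: one molecule in, one scalar out.

    Subclasses set ``family`` and implement :meth:`compute`; ``name`` must be
    unique within a calculator. Descriptors support arithmetic (``+``, ``-``,
    ``*``, ``/``, ``**``, unary ``-``) yielding composite descriptors whose
    operands propagate missing values.
    """

    family: str = ""
    #: preprocessing every in-scope descriptor agrees on: hydrogen-suppressed
    policy = PreprocessPolicy(explicit_hydrogens="remove")

    @property
    def name(self) -> str:
        raise NotImplementedError

    def parameters(self) -> dict[str, Any]:
        return {}

    def compute(self, mol: MolecularGraph, ctx: Context) -> Any:
        raise NotImplementedError

    def __repr__(self) -> str:
        return self.name

    # -- descriptor arithmetic ------------------------------------------

    def __add__(self, other):
        return BinaryComposite("+", self, other)

    def __radd__(self, other):
        return BinaryComposite("+", other, self)

    def __sub__(self, other):
        return BinaryComposite("-", self, other)

    def __rsub__(self, other):
        return BinaryComposite("-", other, self)

    def __mul__(self, other):
        return BinaryComposite("*", self, other)

    def __rmul__(self, other):
        return BinaryComposite("*", other, self)

    def __truediv__(self, other):
        return BinaryComposite("/", self, other)

    def __rtruediv__(self, other):
        return BinaryComposite("/", other, self)

    def __pow__(self, other):
        return BinaryComposite("**", self, other)

    def __neg__(self):
        return UnaryComposite("-", self)


_BINARY_OPS: dict[str, Callable[[float, float], float]] = {
    "+": lambda a, b: a + b,
    "-": lambda a, b: a - b,
    "*": lambda a, b: a * b,
    "/": lambda a, b: a / b,
    "**": lambda a, b: a ** b,
}


def _operand_value(operand: Any, ctx: Context) -> Any:
    if isinstance(operand, Descriptor):
        return ctx.descriptor_value(operand)
    return operand


def _operand_name(operand: Any) -> str:
    if isinstance(operand, Descriptor):
        return operand.name
    return repr(operand)


class BinaryComposite(Descriptor):
    """Descriptor built from two operands and a binary operator."""

    family = "Composite"

    def __init__(self, op: str, left: Any, right: Any) -> None:
        if op not in _BINARY_OPS:
            raise ValueError(f"unknown operator {op!r}")
        if not isinstance(left, (Descriptor, numbers.Real)) or not isinstance(
            right, (Descriptor, numbers.Real)
        ):
            raise TypeError("operands must be descriptors or real constants")
        self.op = op
        self.left = left
        self.right = right

    @property
    def name(self) -> str:
        return f"({_operand_name(self.left)} {self.op} {_operand_name(self.right)})"

    def parameters(self) -> dict[str, Any]:
        return {"op": self.op}

    def compute(self, mol: MolecularGraph, ctx: Context) -> Any:
        a = _operand_value(self.left, ctx)
        b = _operand_value(self.right, ctx)
        for v in (a, b):
            if isinstance(v, MissingValue):
                return MissingValue(
                    MissingReason.dependency_failure,
                    f"operand {v.descriptor or '?'} missing ({v.reason.value})",
                    self.name,
                )
        return _BINARY_OPS[self.op](float(a), float(b))


class UnaryComposite(Descriptor):
    family = "Composite"

    def __init__(self, op: str, operand: Descriptor) -> None:
        if op != "-":
            raise ValueError(f"unknown unary operator {op!r}")
        self.op = op
        self.operand = operand

    @property
    def name(self) -> str:
        return f"(-{_operand_name(self.operand)})"

    def compute(self, mol: MolecularGraph, ctx: Context) -> Any:
        v = _operand_value(self.operand, ctx)
        if isinstance(v, MissingValue):
            return MissingValue(
                MissingReason.dependency_failure,
                f"operand {v.descriptor or '?'} missing ({v.reason.value})",
                self.name,
            )
        return -float(v)


class ResultSet:
    """Ordered mapping descriptor-name -> value-or-missing for one molecule."""

    def __init__(self, molecule_name: str, entries: Sequence[tuple[str, Any]]) -> None:
        self.molecule_name = molecule_name
        self._names = tuple(name for name, _ in entries)
        self._values = tuple(value for _, value in entries)

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    def values(self) -> tuple[Any, ...]:
        return self._values

    def items(self) -> Iterator[tuple[str, Any]]:
        return iter(zip(self._names, self._values))

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[Any]:
        return iter(self._values)

    def __getitem__(self, key: str | int) -> Any:
        if isinstance(key, int):
            return self._values[key]
        try:
            return self._values[self._names.index(key)]
        except ValueError:
            raise KeyError(key) from None

    def missing(self) -> list[MissingValue]:
        return [v for v in self._values if isinstance(v, MissingValue)]

    def fill_missing(self, fill: float = float("nan")) -> "ResultSet":
        """Replace every missing value by a numeric sentinel (default NaN)."""
        return ResultSet(
            self.molecule_name,
            [
                (n, fill if isinstance(v, MissingValue) else v)
                for n, v in self.items()
            ],
        )

    def drop_missing(self) -> "ResultSet":
        return ResultSet(
            self.molecule_name,
            [(n, v) for n, v in self.items() if not isinstance(v, MissingValue)],
        )

    def asdict(self) -> dict[str, Any]:
        """Plain name -> value mapping preserving registration order."""
        return dict(self.items())

    as_mapping = asdict

    def __repr__(self) -> str:
        return f"ResultSet({self.molecule_name!r}, {len(self)} descriptors)"


def _coerce_molecule(item: Any) -> MolecularGraph:
    if isinstance(item, MolecularGraph):
        return item
    if isinstance(item, str):
        from .io import read_molecules

        mols = read_molecules(item, format="smiles")
        if len(mols) != 1:
            raise ValueError(f"expected one molecule, got {len(mols)} from {item!r}")
        return mols[0]
    raise TypeError(f"cannot interpret {type(item).__name__} as a molecule")


class Calculator(BaseEstimator, TransformerMixin):
    """Ordered descriptor registry and batch evaluator.

    Parameters
    ----------
    descriptors:
        What to compute: ``"all"`` (every in-scope family preset), a family
        name, a :class:`Descriptor`, or a list mixing these. ``None`` starts
        empty for imperative :meth:`register` use.
    n_jobs:
        Worker processes for :meth:`transform` / :meth:`map`; results are
        identical to serial evaluation, in input order.
    strict:
        Re-raise the underlying exception instead of returning a
        :class:`MissingValue` (debugging aid).
    use_cache:
        Per-molecule shared-intermediate cache; disabling it never changes
        values.
    """

    def __init__(
        self,
        descriptors: Any = None,
        n_jobs: int = 1,
        strict: bool = False,
        use_cache: bool = True,
    ) -> None:
        self.descriptors = descriptors
        self.n_jobs = n_jobs
        self.strict = strict
        self.use_cache = use_cache
        self._registered: list[Descriptor] | None = None

    # -- registry --------------------------------------------------------

    def _resolve_item(self, item: Any) -> list[Descriptor]:
        from .descriptors import all_presets, preset

        if item is None:
            return []
        if isinstance(item, Descriptor):
            return [item]
        if isinstance(item, str):
            if item == "all":
                return all_presets()
            return preset(item)
        if isinstance(item, Iterable):
            out: list[Descriptor] = []
            for sub in item:
                out.extend(self._resolve_item(sub))
            return out
        raise TypeError(f"cannot register {type(item).__name__}")

    @property
    def registered(self) -> list[Descriptor]:
        if self._registered is None:
            self._registered = []
            self._register_checked(self._resolve_item(self.descriptors))
        return self._registered

    def _register_checked(self, descs: list[Descriptor]) -> None:
        assert self._registered is not None
        names = {d.name for d in self._registered}
        for d in descs:
            if d.name in names:
                raise ValueError(f"duplicate descriptor name {d.name!r}")
            names.add(d.name)
            self._registered.append(d)

    def register(self, item: Any) -> "Calculator":
        """Append a descriptor, family preset or list; registration order kept."""
        _ = self.registered  # force resolution of the init argument first
        self._register_checked(self._resolve_item(item))
        return self

    @property
    def descriptor_names(self) -> list[str]:
        return [d.name for d in self.registered]

    def __len__(self) -> int:
        return len(self.registered)

    # -- evaluation ------------------------------------------------------

    def calculate(self, mol: Any) -> ResultSet:
        """Evaluate every registered descriptor on one molecule.

        Failures are contained as :class:`MissingValue` entries (unless
        ``strict``); the result always has one entry per registered
        descriptor, in registration order.
        """
        mol = _coerce_molecule(mol)
        prepped = (
            mol
            if mol.parse_error is not None
            else preprocess(mol, Descriptor.policy)
        )
        ctx = Context(prepped, use_cache=self.use_cache)
        entries: list[tuple[str, Any]] = []
        for desc in self.registered:
            value = ctx.descriptor_value(desc)
            if self.strict and isinstance(value, MissingValue):
                raise RuntimeError(f"{desc.name}: {value.reason.value} {value.message}")
            entries.append((desc.name, value))
        return ResultSet(mol.name, entries)

    __call__ = calculate

    def map(self, mols: Sequence[Any], processes: int | None = None) -> list[ResultSet]:
        """Evaluate a batch; order preserved, identical to serial results."""
        mols = [_coerce_molecule(m) for m in mols]
        procs = self.n_jobs if processes is None else processes
        if procs < 1:
            raise ValueError("processes must be >= 1")
        _ = self.registered  # resolve before forking
        if procs == 1 or len(mols) <= 1:
            return [self.calculate(m) for m in mols]
        chunksize = max(1, math.ceil(len(mols) / (4 * procs)))
        with get_context("fork").Pool(procs) as pool:
            return pool.map(self.calculate, mols, chunksize=chunksize)

    # -- scikit-learn transformer surface --------------------------------

    def fit(self, X: Sequence[Any] | None = None, y: Any = None) -> "Calculator":
        """Freeze the descriptor list; molecules themselves need no fitting."""
        self.descriptors_ = list(self.registered)
        self.feature_names_ = [d.name for d in self.descriptors_]
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Sequence[Any]) -> np.ndarray:
        """(n_molecules, n_descriptors) float matrix; missing -> NaN."""
        if not hasattr(self, "descriptors_"):
            self.fit(X)
        results = self.map(list(X))
        return np.array(
            [[float(v) for v in r.fill_missing()] for r in results], dtype=float
        )

    def get_feature_names_out(self, input_features: Any = None) -> np.ndarray:
        names = getattr(self, "feature_names_", None) or self.descriptor_names
        return np.asarray(names, dtype=object)

    def to_dataframe(self, mols: Sequence[Any], processes: int | None = None):
        """Batch results as a pandas DataFrame indexed by molecule name."""
        import pandas as pd

        results = self.map(mols, processes=processes)
        frame = pd.DataFrame(
            [[float(v) for v in r.fill_missing()] for r in results],
            columns=self.descriptor_names,
            index=[r.molecule_name for r in results],
        )
        frame.index.name = "name"
        return frame
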