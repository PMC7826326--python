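"""Configurable sampling distributions for valences and decay parameters.

Named distributions are resolved against :mod:`scipy.stats`.  The
interference models compare valences with strict inequalities and assume
the comparison is almost surely decisive, so valence distributions must be
continuous (atom-free); configurations carrying point masses are rejected
rather than given arbitrary tie semantics.  The linear-decay model instead
requires non-negative support for the initial strength ``a`` and the decay
rate ``b`` (a degenerate ``constant`` distribution is allowed there, e.g.
``b = 0`` for non-decaying memories).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import stats
from scipy.stats import rv_continuous

__all__ = [
    "DistributionSpec",
    "Constant",
    "resolve_distribution",
    "require_continuous",
    "require_nonnegative",
]


class Constant:
    """Degenerate distribution concentrated at a single value.

    Provided for the linear-decay model (e.g. a zero decay rate); it is not
    a valid valence distribution because it carries an atom.
    """

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None) -> np.ndarray:
        return np.full(size if size is not None else (), self.value)

    def support(self) -> tuple[float, float]:
        return (self.value, self.value)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Constant({self.value})"


@dataclass(frozen=True)
class DistributionSpec:
    """A named distribution plus keyword parameters.

    ``name`` is either ``"constant"`` (with a ``value`` parameter) or the
    name of a continuous distribution in :mod:`scipy.stats`; ``params`` are
    passed through to freeze it (``loc``, ``scale``, shape parameters).
    """

    name: str
    params: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"name": self.name, "params": dict(self.params)}

    @staticmethod
    def from_any(obj) -> "DistributionSpec":
        if isinstance(obj, DistributionSpec):
            return obj
        if isinstance(obj, Mapping):
            return DistributionSpec(obj["name"], dict(obj.get("params", {})))
        raise TypeError(f"cannot interpret {obj!r} as a distribution spec")


def resolve_distribution(spec):
    """Return a frozen scipy distribution (or :class:`Constant`) for ``spec``.

    ``spec`` may already be a frozen scipy distribution or a
    :class:`Constant`, in which case it is returned unchanged.
    """
    if isinstance(spec, (Constant, stats.distributions.rv_frozen)):
        return spec
    spec = DistributionSpec.from_any(spec)
    if spec.name == "constant":
        return Constant(spec.params.get("value", 0.0))
    dist = getattr(stats, spec.name, None)
    if dist is None:
        raise ValueError(f"unknown distribution {spec.name!r}")
    return dist(**spec.params)


def require_continuous(dist, role: str = "valence"):
    """Reject distributions with positive tie probability.

    The erasure rules are defined through strict dominance comparisons;
    an atom-carrying distribution would make ties occur with positive
    probability and the model does not define their semantics.
    """
    if isinstance(dist, Constant) or not isinstance(
        getattr(dist, "dist", None), rv_continuous
    ):
        raise ValueError(
            f"{role} distribution must be continuous (atom-free); "
            f"got {dist!r} which admits ties with positive probability"
        )
    return dist


def require_nonnegative(dist, role: str):
    """Reject distributions whose support extends below zero."""
    lo, _ = dist.support()
    if lo < 0:
        raise ValueError(
            f"{role} distribution must have non-negative support; "
            f"support starts at {lo}"
        )
    return dist
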