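"""Metric value semantics, including the distinguished UNDEFINED state.

Several confusion-matrix rates have the shape x/(x+y) and possess no limit
at (0, 0): approaching along y = 0 gives 1, along x = 0 gives 0, and along
y = (1-t)/t * x gives t for any t in (0, 1).  There is therefore no
meaningful number such a rate can be set to when its denominator vanishes,
and silently substituting 0 or 0.5 would be wrong.  ``UNDEFINED`` is a
distinguished sentinel for this state: it propagates through arithmetic
(so derived metrics such as BM = TPR + TNR - 1 become undefined exactly
when an ingredient is) and refuses ordering comparisons with a typed
error, so an undefined score can never silently win or lose a ranking.
"""

from __future__ import annotations

from typing import TypeGuard, Union


class UndefinedComparisonError(TypeError):
    """Raised when an UNDEFINED metric value is ordered or coerced."""


class _Undefined:
    """Singleton sentinel for metric values with vanishing denominators.

    Absorbing under arithmetic; ordering comparisons and numeric coercion
    raise :class:`UndefinedComparisonError`.  Serialized as ``"undefined"``.
    """

    _instance: "_Undefined | None" = None
    __slots__ = ()

    def __new__(cls) -> "_Undefined":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "undefined"

    def __reduce__(self):
        return (_Undefined, ())

    # -- absorbing arithmetic -------------------------------------------
    def _absorb(self, *_args) -> "_Undefined":
        return self

    __add__ = __radd__ = _absorb
    __sub__ = __rsub__ = _absorb
    __mul__ = __rmul__ = _absorb
    __truediv__ = __rtruediv__ = _absorb
    __pow__ = __rpow__ = _absorb
    __neg__ = __pos__ = __abs__ = _absorb
    __round__ = _absorb

    # -- comparisons -----------------------------------------------------
    def _refuse(self, *_args):
        raise UndefinedComparisonError(
            "UNDEFINED metric values cannot be ordered; check is_defined() first"
        )

    __lt__ = __le__ = __gt__ = __ge__ = _refuse

    def __bool__(self) -> bool:
        self._refuse()

    def __float__(self) -> float:
        self._refuse()

    def __eq__(self, other: object) -> bool:
        return other is self

    def __ne__(self, other: object) -> bool:
        return other is not self

    def __hash__(self) -> int:
        return hash("cmeval.UNDEFINED")


UNDEFINED = _Undefined()

#: A metric value: a float in the metric's range, or UNDEFINED.
MetricValue = Union[float, _Undefined]


def is_defined(value: MetricValue) -> TypeGuard[float]:
    """True when *value* is an actual number rather than UNDEFINED."""
    return value is not UNDEFINED


def format_value(value: MetricValue, precision: int | None = 3) -> str:
    """Render a metric value for display/CSV; UNDEFINED becomes ``undefined``."""
    if not is_defined(value):
        return "undefined"
    if precision is None:
        return repr(float(value))
    return f"{value:.{precision}f}"
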