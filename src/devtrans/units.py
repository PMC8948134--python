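"""Minimal unit algebra for dimensional-consistency checking.

Units are products/quotients of named base units with integer exponents
(e.g. ``CVU/year``, ``FSU*year^-1``); ``dimensionless`` (or ``1``) is the
empty product.  Pure ratios of like units cancel to dimensionless.
"""
from __future__ import annotations

import re


class UnitSyntaxError(ValueError):
    """A unit expression could not be parsed."""


_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z_0-9]*|1)\s*(?:\^\s*(-?\d+))?\s*")


class Unit:
    """Immutable product of base units with integer exponents."""

    __slots__ = ("_exps",)

    def __init__(self, exps: dict[str, int] | None = None):
        exps = {k: int(v) for k, v in (exps or {}).items() if v != 0}
        object.__setattr__(self, "_exps", tuple(sorted(exps.items())))

    @property
    def exps(self) -> dict[str, int]:
        return dict(self._exps)

    def __mul__(self, other: "Unit") -> "Unit":
        out = self.exps
        for k, v in other.exps.items():
            out[k] = out.get(k, 0) + v
        return Unit(out)

    def __truediv__(self, other: "Unit") -> "Unit":
        out = self.exps
        for k, v in other.exps.items():
            out[k] = out.get(k, 0) - v
        return Unit(out)

    def __pow__(self, n: int) -> "Unit":
        return Unit({k: v * n for k, v in self.exps.items()})

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Unit) and self._exps == other._exps

    def __hash__(self) -> int:
        return hash(self._exps)

    @property
    def is_dimensionless(self) -> bool:
        return not self._exps

    def __repr__(self) -> str:
        return f"Unit({str(self)!r})"

    def __str__(self) -> str:
        if not self._exps:
            return "dimensionless"
        num = [k if e == 1 else f"{k}^{e}" for k, e in self._exps if e > 0]
        den = [k if e == -1 else f"{k}^{-e}" for k, e in self._exps if e < 0]
        if not num:
            num = ["1"]
        s = "*".join(num)
        if den:
            s += "/" + "/".join(den)
        return s


DIMENSIONLESS = Unit()
YEAR = Unit({"year": 1})


def parse_units(text: str) -> Unit:
    """Parse a unit string such as ``"CVU/year"`` into a :class:`Unit`.

    Grammar: ``term (('*'|'/') term)*`` with ``term := name ('^' int)?``;
    the literal names ``dimensionless`` and ``1`` denote the empty product.
    Left-associative, so ``a/b*c`` means ``(a/b)*c``.
    """
    if not isinstance(text, str) or not text.strip():
        raise UnitSyntaxError(f"empty or non-string unit expression: {text!r}")
    pos = 0
    sign = 1
    result = Unit()
    text = text.strip()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise UnitSyntaxError(f"cannot parse unit expression {text!r} at position {pos}")
        name, exp = m.group(1), int(m.group(2) or 1)
        if name not in ("dimensionless", "1"):
            result = result * Unit({name: sign * exp})
        pos = m.end()
        if pos < len(text):
            op = text[pos]
            if op == "*":
                sign = 1
            elif op == "/":
                sign = -1
            else:
                raise UnitSyntaxError(f"unexpected character {op!r} in unit expression {text!r}")
            pos += 1
            if pos >= len(text):
                raise UnitSyntaxError(f"dangling operator in unit expression {text!r}")
    return result
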