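"""Variance-component containers shared by the generator and the SEM.

A phenotype's variance is decomposed into additive-genetic (A), shared- or
common-environmental (C), unique-environmental (E, which absorbs measurement
error) and data-collection-site (S) parts.  A is correlated 1.0 between
monozygotic co-twins and 0.5 between dizygotic co-twins or full siblings;
C is shared by all members of a family; S by all members of a site; E is
person-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VarianceComponents", "COMPONENTS"]

COMPONENTS = ("A", "C", "E", "S")


@dataclass(frozen=True)
class VarianceComponents:
    """A/C/E/S variances of one phenotype (or of one structural residual).

    ``var_c`` and ``var_s`` may be negative in fitted models (a negative C
    estimate can indicate non-additive genetic variance); ``var_e`` must be
    positive because it carries measurement error.
    """

    var_a: float
    var_c: float
    var_e: float
    var_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.var_e > 0:
            raise ValueError(f"var_e must be > 0, got {self.var_e}")

    @property
    def total(self) -> float:
        return self.var_a + self.var_c + self.var_e + self.var_s

    def proportions(self) -> dict[str, float]:
        """VA/VC/VE/VS: each component divided by the component sum."""
        t = self.total
        if not t > 0:
            raise ValueError("total variance must be > 0")
        return {
            "VA": self.var_a / t,
            "VC": self.var_c / t,
            "VE": self.var_e / t,
            "VS": self.var_s / t,
        }

    def as_dict(self) -> dict[str, float]:
        return {
            "A": self.var_a,
            "C": self.var_c,
            "E": self.var_e,
            "S": self.var_s,
        }

    @classmethod
    def from_proportions(
        cls, va: float, vc: float, ve: float, vs: float = 0.0, total: float = 1.0
    ) -> "VarianceComponents":
        """Build components from proportions, rescaled to sum to ``total``.

        Proportions that do not sum to exactly 1 (e.g. rounded published
        values) are renormalized.
        """
        s = va + vc + ve + vs
        if not s > 0:
            raise ValueError("proportions must sum to a positive value")
        f = total / s
        return cls(va * f, vc * f, ve * f, vs * f)
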