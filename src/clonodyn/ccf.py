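"""Deterministic mapping between cancer-cell fraction (CCF) and expected VAF.

A bulk tumour sample is a mixture of three cell populations with respect to a
given somatic mutation: normal cells (diploid, no mutation), a reference cancer
population without the mutation, and a variant cancer population carrying it.
The expected variant allele fraction of a mutation is the fraction of
chromosome copies carrying the alternative allele across this mixture; purity
and local copy number determine the linear coefficient relating VAF to CCF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocusContext",
    "expected_vaf_general",
    "clonal_vaf_coefficient",
    "expected_vaf_simplified",
    "estimate_multiplicity",
]


@dataclass(frozen=True)
class LocusContext:
    """Per-locus, per-sample quantities needed to convert CCF to expected VAF.

    Parameters
    ----------
    purity
        Fraction of cells in the sample that are cancerous, in (0, 1].
    copy_number
        Total copy number shared by the reference and variant cancer
        populations at this locus (the usual no-subclonal-CNV simplification).
    multiplicity
        Number of chromosome copies per variant cell carrying the mutation,
        1 <= multiplicity <= copy_number.
    copy_number_ref, copy_number_var
        Copy numbers of the reference and variant cancer populations for the
        general three-population form; default to ``copy_number``.
    """

    purity: float
    copy_number: int = 2
    multiplicity: int = 1
    copy_number_ref: int | None = None
    copy_number_var: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be a positive integer")
        d_var = self.copy_number_var if self.copy_number_var is not None else self.copy_number
        if not 1 <= self.multiplicity <= d_var:
            raise ValueError(
                f"multiplicity must satisfy 1 <= d <= {d_var}, got {self.multiplicity}"
            )

    @property
    def d_ref(self) -> int:
        return self.copy_number_ref if self.copy_number_ref is not None else self.copy_number

    @property
    def d_var(self) -> int:
        return self.copy_number_var if self.copy_number_var is not None else self.copy_number


def expected_vaf_general(ccf: float, ctx: LocusContext) -> float:
    """Expected VAF under the full three-population mixture.

    theta = d^V rho ccf / (2(1-rho) + D^R rho (1-ccf) + D^V rho ccf).
    """
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"ccf must be in [0, 1], got {ccf}")
    rho = ctx.purity
    denom = 2.0 * (1.0 - rho) + ctx.d_ref * rho * (1.0 - ccf) + ctx.d_var * rho * ccf
    if denom <= 0.0:
        raise ValueError("degenerate cell mixture: zero chromosome count in denominator")
    return ctx.multiplicity * rho * ccf / denom


def clonal_vaf_coefficient(ctx: LocusContext) -> float:
    """Expected VAF of a clonal mutation (CCF = 1): zeta = d rho / (2(1-rho) + D rho).

    Under the shared-copy-number simplification the VAF is linear in CCF with
    slope zeta, so this coefficient fully determines the mapping.
    """
    rho = ctx.purity
    denom = 2.0 * (1.0 - rho) + ctx.copy_number * rho
    return ctx.multiplicity * rho / denom


def expected_vaf_simplified(ccf, ctx: LocusContext):
    """Linearized expected VAF, theta = zeta * ccf (shared copy number)."""
    return clonal_vaf_coefficient(ctx) * np.asarray(ccf, dtype=float)


def estimate_multiplicity(vaf_obs: float, purity: float, copy_number: int) -> int:
    """Estimate the integer mutation multiplicity from an observed VAF.

    Computes u = vaf * rho^-1 * (2(1-rho) + D rho), the product of multiplicity
    and CCF, then takes the closest integer when u >= 1 and 1 otherwise.
    Half-way ties round away from zero; the result is clamped to [1, D] since
    noisy VAFs can push u above the local copy number.
    """
    if purity <= 0.0:
        raise ValueError("purity must be positive")
    if copy_number < 1:
        raise ValueError("copy_number must be a positive integer")
    u = vaf_obs / purity * (2.0 * (1.0 - purity) + copy_number * purity)
    if u < 1.0:
        return 1
    d = int(np.floor(u + 0.5))  # round half away from zero (u > 0 here)
    return min(d, copy_number)
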