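"""Closed-form steady-state model of transcript competition for free ribosomes.

A transcript initiates at rate ``ki * R`` (``R`` = free-ribosome level) but
only when its start codon is not occluded by an elongating ribosome.  At
steady state the probability that the first ``L`` codons are clear is

    p_clear = 1 - L / (ke/(ki*R) + L - 1)

so the protein production rate of a transcript present at ``m`` copies is

    Q = m * R * ki * p_clear.

Only dimensionless combinations are meaningful; the natural control variable
is ``x = ki*R/ke``.  The model is valid for ``x <= 1``; at ``x = 1`` the
lattice jams and ``Q = 0`` exactly.  ``x > 1`` is outside the model's domain
and raises :class:`JammedRegimeError` rather than being clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TranscriptParams",
    "YieldResult",
    "JammedRegimeError",
    "start_clearance_probability",
    "protein_yield",
    "yield_ratio",
    "yield_curve",
]


class JammedRegimeError(ValueError):
    """Raised when ke/(ki*R) < 1: the start codon can never clear."""


@dataclass(frozen=True)
class TranscriptParams:
    """Kinetic parameters of one transcript species.

    Parameters
    ----------
    gene_id : str
        Identifier, carried through all outputs.
    ki : float
        Initiation rate constant, per free-ribosome unit per time unit.
    ke : float
        Elongation rate, codons per time unit.
    m : float
        mRNA abundance (copies, arbitrary units).
    L : int
        Ribosome footprint, codons.
    n_codons : int
        Coding length, codons; must be >= L.
    charge_profile : numpy array of {0,1}, optional
        Per-residue indicator of a positively charged amino acid (K/R),
        length ``n_codons``.  Used only by the stochastic simulator.
    """

    gene_id: str
    ki: float
    ke: float
    m: float
    L: int = 10
    n_codons: int = 300
    charge_profile: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.ki > 0:
            raise ValueError(f"{self.gene_id}: ki must be > 0, got {self.ki}")
        if not self.ke > 0:
            raise ValueError(f"{self.gene_id}: ke must be > 0, got {self.ke}")
        if self.m < 0:
            raise ValueError(f"{self.gene_id}: m must be >= 0, got {self.m}")
        if int(self.L) != self.L or self.L < 1:
            raise ValueError(f"{self.gene_id}: L must be an integer >= 1, got {self.L}")
        if int(self.n_codons) != self.n_codons or self.n_codons < self.L:
            raise ValueError(
                f"{self.gene_id}: n_codons must be an integer >= L, got {self.n_codons}"
            )
        if self.charge_profile is not None:
            cp = np.asarray(self.charge_profile)
            if cp.shape != (self.n_codons,):
                raise ValueError(
                    f"{self.gene_id}: charge_profile length {cp.shape} != n_codons {self.n_codons}"
                )
            if not np.isin(cp, (0, 1)).all():
                raise ValueError(f"{self.gene_id}: charge_profile values must be 0/1")
            object.__setattr__(self, "charge_profile", cp.astype(np.int8))


@dataclass(frozen=True)
class YieldResult:
    """Steady-state output for one transcript at one free-ribosome level."""

    Q: float            # protein production rate (proteins / time unit)
    p_clear: float      # probability the start codon is clear
    load_per_mrna: float  # expected elongating ribosomes per mRNA copy


def _check_domain(t: TranscriptParams, R: float) -> float:
    if not R > 0:
        raise JammedRegimeError(f"{t.gene_id}: free-ribosome level must be > 0, got {R}")
    ratio = t.ke / (t.ki * R)
    if ratio < 1.0:
        raise JammedRegimeError(
            f"{t.gene_id}: jammed regime ke/(ki*R) = {ratio:.6g} < 1 "
            f"(ki={t.ki:.6g}, ke={t.ke:.6g}, R={R:.6g})"
        )
    return ratio


def start_clearance_probability(t: TranscriptParams, R: float) -> float:
    """Probability that the initiation region (first L codons) is clear.

    Returns ``1 - L/(ke/(ki*R) + L - 1)``, which is 0 at the jamming
    boundary ``ke/(ki*R) = 1`` and tends to 1 as elongation becomes fast.
    """
    ratio = _check_domain(t, R)
    p = 1.0 - t.L / (ratio + t.L - 1.0)
    # ratio >= 1 guarantees p in [0, 1]; clip rounding at the boundary only
    return min(max(p, 0.0), 1.0)


def protein_yield(t: TranscriptParams, R: float) -> YieldResult:
    """Protein production rate Q = m*R*ki*p_clear and per-copy ribosome load.

    The per-copy load follows Little's law: initiation flux per copy
    ``J = Q/m = R*ki*p_clear`` times the transit time ``n_codons/ke``.
    """
    p = start_clearance_probability(t, R)
    flux_per_copy = R * t.ki * p
    return YieldResult(
        Q=t.m * flux_per_copy,
        p_clear=p,
        load_per_mrna=flux_per_copy * t.n_codons / t.ke,
    )


def yield_ratio(
    t1: TranscriptParams,
    t2: TranscriptParams,
    R: float,
    use_abundance: bool = False,
) -> float:
    """Ratio Q1/Q2 of two transcripts at the same free-ribosome level.

    By default the comparison is at equal mRNA abundance (m factored out);
    pass ``use_abundance=True`` to weight by each transcript's own ``m``.
    """
    y1, y2 = protein_yield(t1, R), protein_yield(t2, R)
    if use_abundance:
        q1, q2 = y1.Q, y2.Q
    else:
        q1 = R * t1.ki * y1.p_clear
        q2 = R * t2.ki * y2.p_clear
    if q2 == 0.0:
        raise ZeroDivisionError(
            f"yield_ratio: denominator transcript {t2.gene_id} has zero yield at R={R}"
        )
    return q1 / q2


def yield_curve(t: TranscriptParams, R_grid: Sequence[float]) -> list[YieldResult]:
    """Elementwise :func:`protein_yield` over a grid of free-ribosome levels.

    Domain errors are re-raised with the offending grid index.
    """
    out: list[YieldResult] = []
    for i, R in enumerate(R_grid):
        try:
            out.append(protein_yield(t, R))
        except JammedRegimeError as e:
            raise JammedRegimeError(f"grid index {i} (R={R}): {e}") from e
    return out
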