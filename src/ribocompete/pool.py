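"""Whole-transcriptome ribosome bookkeeping.

Closes the single-transcript model with a conservation law: ribosomes are
either free or elongating, so the free level ``R_free`` must satisfy

    R_free + sum_g m_g * load_per_mrna(g, R_free) = R_total.

Elongation-factor knockdown is modelled through the two-phase codon dwell:
each codon advance waits for an eEF2 molecule (rate proportional to the
availability fraction ``E``, identical for all transcripts) and then
translocates (rate slowed by positive residues in the exit tunnel,
sequence specific).  The per-gene effective elongation rate is

    ke_g(E) = 2 * ke / (1/E + A_g),   A_g = mean_i exp(beta * q_i)

so that an uncharged transcript at full availability recovers its nominal
``ke``.  Depletion therefore slows charge-rich transcripts *less* in
relative terms — their translocation was already slow, and the shared
waiting time dominates everyone's dwell.  Combined with pool conservation
this shifts both ribosome load and protein synthesis toward the TOP-like
class (high initiation, charge-rich, elongation-limited at baseline).
A plain uniform scaling ``ke' = f * ke`` is available by passing
``elongation=None`` to the scenario.

Polysome-gradient classes (free / monosome / light 2-4 / heavy >4
ribosomes per mRNA) are predicted from a truncated-Poisson load
distribution per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import JammedRegimeError, TranscriptParams, protein_yield

__all__ = [
    "PoolState",
    "PolysomeProfile",
    "ElongationModel",
    "KnockdownScenario",
    "KnockdownResult",
    "total_bound",
    "solve_free_ribosomes",
    "polysome_fractions",
    "simulate_knockdown",
]


@dataclass(frozen=True)
class PoolState:
    """Solved whole-cell ribosome allocation."""

    R_total: float
    R_free: float
    E: float = 1.0  # residual elongation-factor availability fraction

    def __post_init__(self) -> None:
        if not (0.0 <= self.R_free <= self.R_total):
            raise ValueError(f"R_free={self.R_free} outside [0, R_total={self.R_total}]")
        if not (0.0 < self.E <= 1.0):
            raise ValueError(f"E={self.E} outside (0, 1]")


@dataclass(frozen=True)
class PolysomeProfile:
    """Fractions of total ribosome signal by sucrose-gradient class.

    ``free_frac`` counts ribosomes not engaged on mRNA; ``mono_frac``
    mRNAs carrying exactly 1 ribosome; ``light_frac`` 2-4; ``heavy_frac``
    more than 4.  An mRNA carrying j ribosomes contributes j ribosome
    units of signal.  ``mono_to_poly`` = mono/(light+heavy); when no
    polysomal signal exists it is the sentinel ``inf`` with
    ``mono_to_poly_capped`` set.
    """

    free_frac: float
    mono_frac: float
    light_frac: float
    heavy_frac: float
    mono_to_poly: float
    mono_to_poly_capped: bool = False

    def __post_init__(self) -> None:
        fr = (self.free_frac, self.mono_frac, self.light_frac, self.heavy_frac)
        if min(fr) < -1e-12:
            raise ValueError(f"negative class fraction: {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {sum(fr)}, not 1")


@dataclass(frozen=True)
class ElongationModel:
    """Two-phase codon dwell mapping factor availability E to effective ke.

    Per codon, the expected dwell is ``1/(2*ke*E) + 1/(2*ke*exp(-beta*q_i))``
    (waiting + translocation), so ``ke_g(E) = 2*ke / (1/E + A_g)`` with
    ``A_g`` the mean of ``exp(beta*q_i)`` over codons; ``q_i`` counts
    positive residues among the W residues preceding codon i.  Uncharged
    transcripts at E = 1 recover their nominal ke exactly.
    """

    beta: float = 0.3  # translocation penalty per positive residue
    W: int = 10        # exit-tunnel window, residues

    def charge_factor(self, t: TranscriptParams) -> float:
        """A_g >= 1; equals 1 for uncharged transcripts."""
        if t.charge_profile is None or self.beta == 0.0:
            return 1.0
        cp = np.asarray(t.charge_profile, dtype=float)
        cum = np.concatenate(([0.0], np.cumsum(cp)))
        pos = np.arange(t.n_codons)
        q = cum[pos] - cum[np.maximum(0, pos - self.W)]
        return float(np.mean(np.exp(self.beta * q)))

    def effective_ke(self, t: TranscriptParams, E: float) -> float:
        return 2.0 * t.ke / (1.0 / E + self.charge_factor(t))


@dataclass(frozen=True)
class KnockdownScenario:
    """Elongation-factor depletion to a residual availability fraction f.

    With the default charge-aware :class:`ElongationModel`, both baseline
    (E = 1) and knockdown (E = f) use per-gene effective elongation rates.
    With ``elongation=None`` the baseline keeps each transcript's nominal
    ke and the knockdown applies the uniform scaling ke' = f * ke.
    """

    depletion_factor: float
    elongation: ElongationModel | None = ElongationModel()

    def __post_init__(self) -> None:
        if not (0.0 < self.depletion_factor <= 1.0):
            raise ValueError(f"depletion_factor must be in (0,1], got {self.depletion_factor}")

    def transcriptomes(
        self, transcriptome: Sequence[TranscriptParams]
    ) -> tuple[list[TranscriptParams], list[TranscriptParams]]:
        """(baseline, knockdown) transcript lists with effective ke applied."""
        f = self.depletion_factor
        if self.elongation is None:
            return list(transcriptome), [replace(t, ke=f * t.ke) for t in transcriptome]
        base = [replace(t, ke=self.elongation.effective_ke(t, 1.0)) for t in transcriptome]
        kd = [replace(t, ke=self.elongation.effective_ke(t, f)) for t in transcriptome]
        return base, kd


def total_bound(transcriptome: Sequence[TranscriptParams], R_free: float) -> float:
    """Total ribosome level sequestered on mRNA at a given free level."""
    if R_free < 0:
        raise ValueError(f"R_free must be >= 0, got {R_free}")
    if R_free == 0.0:
        return 0.0
    tot = 0.0
    for t in transcriptome:
        tot += t.m * protein_yield(t, R_free).load_per_mrna
    return tot


def _valid_upper(transcriptome: Sequence[TranscriptParams], R_total: float):
    """Largest bracketing point inside every gene's valid domain."""
    upper, binding = R_total, None
    for t in transcriptome:
        r_max = t.ke / t.ki  # jamming at R = ke/ki
        if r_max < upper:
            upper, binding = r_max, t.gene_id
    return upper, binding


def solve_free_ribosomes(
    transcriptome: Sequence[TranscriptParams],
    R_total: float,
    rel_tol: float = 1e-10,
    E: float = 1.0,
) -> PoolState:
    """Solve the conservation law for the free-ribosome level.

    Uses a bracketing root finder on [eps, min(R_total, min_g ke/ki)]; the
    residual is re-checked against ``rel_tol`` after convergence.  If the
    conservation root would lie beyond a gene's jamming point, a
    :class:`JammedRegimeError` names that gene.
    """
    if not R_total > 0:
        raise ValueError(f"R_total must be > 0, got {R_total}")
    if not transcriptome or all(t.m == 0 for t in transcriptome):
        return PoolState(R_total=R_total, R_free=R_total, E=E)

    def residual(r: float) -> float:
        return r + total_bound(transcriptome, r) - R_total

    upper, binding = _valid_upper(transcriptome, R_total)
    if binding is not None and residual(upper) < 0:
        raise JammedRegimeError(
            f"conservation root beyond jamming point of gene {binding} "
            f"(valid up to R_free={upper:.6g}, R_total={R_total:.6g})"
        )
    eps = 1e-12 * R_total
    if residual(upper) <= 0:  # binding is None: all bound mass fits at R_total
        r_free = upper
    else:
        r_free = optimize.brentq(residual, eps, upper, xtol=eps, rtol=8.9e-16)
    res = abs(residual(r_free)) / R_total
    if res > max(rel_tol, 1e-8):
        raise RuntimeError(f"conservation residual {res:.3g} exceeds tolerance")
    return PoolState(R_total=R_total, R_free=min(r_free, R_total), E=E)


def _truncated_poisson_class_signal(lam: float, cap: int) -> tuple[float, float, float]:
    """Share of a gene's bound signal in mono (j=1), light (2-4), heavy (>4).

    j ~ Poisson(lam) truncated to 0..cap; an mRNA with j ribosomes carries
    j units of signal, so class shares weight the pmf by j.
    """
    j = np.arange(cap + 1)
    pmf = stats.poisson.pmf(j, lam)
    tot = pmf.sum()
    if tot <= 0.0:
        return (0.0, 0.0, 0.0)
    w = j * pmf / tot
    denom = w.sum()
    if denom <= 0.0:
        return (0.0, 0.0, 0.0)
    mono = w[1] / denom if cap >= 1 else 0.0
    light = w[2 : min(4, cap) + 1].sum() / denom
    heavy = w[5:].sum() / denom
    return (float(mono), float(light), float(heavy))


def polysome_fractions(
    transcriptome: Sequence[TranscriptParams], pool: PoolState
) -> PolysomeProfile:
    """Predicted sucrose-gradient signal fractions at a solved pool state.

    Per gene, ribosomes-per-mRNA-copy is Poisson with mean equal to the
    model load, truncated at the steric capacity floor(n_codons/L).
    """
    free = pool.R_free
    mono = light = heavy = 0.0
    for t in transcriptome:
        if t.m == 0:
            continue
        lam = protein_yield(t, pool.R_free).load_per_mrna
        signal = t.m * lam
        if signal == 0.0:
            continue
        cap = t.n_codons // t.L
        fm, fl, fh = _truncated_poisson_class_signal(lam, cap)
        mono += signal * fm
        light += signal * fl
        heavy += signal * fh
    total = free + mono + light + heavy
    poly = light + heavy
    capped = poly <= 0.0
    m2p = math.inf if capped else mono / poly
    return PolysomeProfile(
        free_frac=free / total,
        mono_frac=mono / total,
        light_frac=light / total,
        heavy_frac=heavy / total,
        mono_to_poly=m2p,
        mono_to_poly_capped=capped,
    )


@dataclass(frozen=True)
class KnockdownResult:
    """Paired baseline / knockdown solution with per-gene yield changes."""

    baseline_pool: PoolState
    knockdown_pool: PoolState
    baseline_profile: PolysomeProfile
    knockdown_profile: PolysomeProfile
    table: pd.DataFrame  # gene_id, ki, Q_baseline, Q_knockdown, log2_rel_yield_change


def simulate_knockdown(
    transcriptome: Sequence[TranscriptParams],
    R_total: float,
    scenario: KnockdownScenario,
) -> KnockdownResult:
    """Re-solve the pool under ke' = f*ke and report relative yield changes.

    Because absolute synthesis drops genome-wide under depletion, the
    per-gene change is relative to the total:
    ``log2[(Q'_g / sum Q') / (Q_g / sum Q)]``.
    """
    f = scenario.depletion_factor
    base_transcriptome, kd_transcriptome = scenario.transcriptomes(transcriptome)

    base_pool = solve_free_ribosomes(base_transcriptome, R_total, E=1.0)
    try:
        kd_pool = solve_free_ribosomes(kd_transcriptome, R_total, E=f)
    except JammedRegimeError as e:
        raise JammedRegimeError(f"knockdown scenario f={f}: {e}") from e

    q_base = np.array([protein_yield(t, base_pool.R_free).Q for t in base_transcriptome])
    q_kd = np.array([protein_yield(t, kd_pool.R_free).Q for t in kd_transcriptome])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.log2((q_kd / q_kd.sum()) / (q_base / q_base.sum()))
    table = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in transcriptome],
            "ki": [t.ki for t in transcriptome],
            "Q_baseline": q_base,
            "Q_knockdown": q_kd,
            "log2_rel_yield_change": rel,
        }
    )
    return KnockdownResult(
        baseline_pool=base_pool,
        knockdown_pool=kd_pool,
        baseline_profile=polysome_fractions(base_transcriptome, base_pool),
        knockdown_profile=polysome_fractions(kd_transcriptome, kd_pool),
        table=table,
    )
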