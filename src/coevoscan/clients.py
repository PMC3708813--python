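"""Steady-state residence times and the Putative Client Index (PCI).

The long-run fraction of time a lineage spends in each joint state
(A, B, C, D) = ((h−,X−), (h+,X−), (h−,X+), (h+,X+)) solves the balance
equations Qᵀπ = 0 with Σπ = 1. The PCI of a partner character is

    PCI = C / ((C + D) · (A + C)),

the residence time in "partner present without the focal character",
normalized by its expectation under independence (marginal probability of
X present times marginal probability of h absent). PCI = 1 exactly when
the rates satisfy the independence restrictions; PCI → 0 when the partner
is (almost) never present without the focal character — the signature of
a strong, conserved chaperone client.

Before solving, zero rates are replaced by 0.001 × the smallest nonzero
rate so the chain is irreducible and the steady state unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, UndefinedScoreError, ValidationError
from .markov import RateParameters, build_generator


@dataclass(frozen=True)
class SteadyStateDistribution:
    """Residence probabilities of the four joint states."""

    A: float  # (h-,X-)
    B: float  # (h+,X-)
    C: float  # (h-,X+)
    D: float  # (h+,X+)

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D])


@dataclass
class ClientScore:
    """Per-character client-index summary across replicate fits."""

    character_id: str
    pci_per_run: list[float]
    pci_mean: float
    n_runs_in_top_set: int
    putative_client: bool


def regularize_rates(rates: RateParameters | np.ndarray) -> RateParameters:
    """Replace zero rates by 0.001 × the smallest nonzero rate.

    Keeps every allowed transition open so the 4-state chain is irreducible.
    Raises :class:`ValidationError` when all rates are zero (no steady state
    is definable).
    """
    arr = rates.as_array() if isinstance(rates, RateParameters) else np.asarray(
        rates, dtype=float
    ).copy()
    if arr.shape != (8,):
        raise ValidationError("expected 8 rates")
    if np.any(arr < 0):
        raise ValidationError("rates must be >= 0")
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValidationError("all rates are zero; steady state undefined")
    floor = 0.001 * nonzero.min()
    out = np.where(arr == 0, floor, arr)
    return RateParameters.from_array(out)


def steady_state(Q: np.ndarray) -> SteadyStateDistribution:
    """Unique stationary distribution of an irreducible 4-state generator.

    Solves the balance equations as a linear system: one equation of
    Qᵀπ = 0 is replaced by the normalization Σπ = 1.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (4, 4):
        raise ValidationError("expected a 4x4 generator")
    M = Q.T.copy()
    M[3, :] = 1.0
    b = np.array([0.0, 0.0, 0.0, 1.0])
    try:
        pi = np.linalg.solve(M, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"balance system is singular: {exc}") from exc
    residual = float(np.max(np.abs(Q.T @ pi)))
    scale = max(1.0, float(np.max(np.abs(Q))))
    if not np.all(np.isfinite(pi)) or residual > 1e-8 * scale:
        raise NumericalError(
            f"ill-conditioned balance system (residual {residual:.3g}); "
            "regularize the rates first"
        )
    if np.any(pi < -1e-12):
        raise NumericalError(f"negative stationary probability in {pi}")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return SteadyStateDistribution(*pi.tolist())


def pci(ss: SteadyStateDistribution) -> float:
    """Putative Client Index C / ((C+D)(A+C)) of a steady state."""
    denom = (ss.C + ss.D) * (ss.A + ss.C)
    if denom <= 0:
        raise UndefinedScoreError(
            "PCI undefined: focal or partner character is never "
            f"present/absent at steady state ({ss})"
        )
    return ss.C / denom


def pci_from_rates(rates: RateParameters | np.ndarray) -> float:
    """Regularize rates, solve the steady state and return the PCI."""
    reg = regularize_rates(rates)
    return pci(steady_state(build_generator(reg)))


def rank_clients(
    pci_per_run: dict[str, list[float]],
    top_k: int,
    agree_threshold: int,
) -> list[ClientScore]:
    """Consensus client calling from per-run PCI values.

    In each replicate run the ``top_k`` characters with the lowest PCI form
    that run's candidate set; a character is a putative client iff it is in
    the candidate set in at least ``agree_threshold`` runs. The returned
    list covers all characters, sorted by mean PCI ascending. Ties at the
    top_k boundary are broken by character order (stable sort).
    """
    chars = list(pci_per_run)
    if not chars:
        return []
    n_runs = len(next(iter(pci_per_run.values())))
    for c in chars:
        if len(pci_per_run[c]) != n_runs:
            raise ValidationError(f"character {c!r} not scored in all runs")
    if top_k > len(chars):
        raise ValidationError(
            f"top_k={top_k} exceeds the {len(chars)} scored characters"
        )
    values = np.array([pci_per_run[c] for c in chars])  # chars × runs
    counts = np.zeros(len(chars), dtype=int)
    for r in range(n_runs):
        in_top = np.argsort(values[:, r], kind="stable")[:top_k]
        counts[in_top] += 1
    means = values.mean(axis=1)
    scores = [
        ClientScore(
            character_id=c,
            pci_per_run=values[i].tolist(),
            pci_mean=float(means[i]),
            n_runs_in_top_set=int(counts[i]),
            putative_client=bool(counts[i] >= agree_threshold),
        )
        for i, c in enumerate(chars)
    ]
    scores.sort(key=lambda s: (s.pci_mean, s.character_id))
    return scores
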