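"""Genome-scale co-evolution screen and dependency-model classification.

Stage 1 (association): for every partner character, the independent
(4-parameter) and mutual (8-parameter) models are fitted and compared with
a likelihood-ratio test, 2·ΔlnL ~ χ² with 4 degrees of freedom (the
difference in free parameters); p-values are corrected across characters
with Benjamini–Hochberg at a chosen FDR. Because single ML runs can land
in different optima, the whole screen is repeated ``n_runs`` times with
different optimizer restarts and a character is called associated only if
it is flagged in at least ``agree_threshold`` runs (the full-scale
convention is 90 of 100; 23 of 25 is a desk-scale equivalent).

Stage 2 (classification): for screen survivors all four dependency models
are fitted and the best model per run is chosen by AIC (ties broken toward
fewer parameters); a character is classified only when the same model wins
in at least ``agree_threshold`` runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .data import CharacterMatrix, PhyloTree
from .errors import DataMismatchError, ValidationError
from .markov import (
    DEFAULT_BOUNDS,
    MODEL_ORDER,
    FitResult,
    RateParameters,
    TreeLikelihood,
    fit_ml,
    joint_states,
)

LRT_DF = 4  # free-parameter difference between the mutual and independent models


@dataclass
class AssociationResult:
    """LRT outcome for one partner character (single run or consensus)."""

    character_id: str
    lnL_independent: float
    lnL_mutual: float
    lr_statistic: float
    p_value: float
    q_value: float
    associated: bool
    n_runs_flagged: int = 1
    n_runs: int = 1


@dataclass
class ClassificationResult:
    """AIC model selection for one character across replicate runs."""

    character_id: str
    fits: dict[str, FitResult]  # best fit per model across runs
    best_model: str
    consensus_count: int
    n_runs: int
    classified: bool
    votes: dict[str, int] = field(default_factory=dict)
    mutual_rates_per_run: list[RateParameters] = field(default_factory=list)


def lrt_association(
    fit_indep: FitResult,
    fit_mutual: FitResult,
    df: int = LRT_DF,
    alpha: float = 0.05,
) -> AssociationResult:
    """Likelihood-ratio test of the mutual against the independent model.

    The statistic is floored at 0 (the models are nested, so a negative
    difference can only be optimizer noise). ``q_value`` is set equal to the
    raw p-value here; multiple-testing correction happens at the screen
    level where all characters are visible.
    """
    if fit_indep.data_hash != fit_mutual.data_hash:
        raise DataMismatchError(
            "independent and mutual fits were made on different data"
        )
    lr = max(0.0, 2.0 * (fit_mutual.log_likelihood - fit_indep.log_likelihood))
    p = float(chi2.sf(lr, df)) if lr > 0 else 1.0
    return AssociationResult(
        character_id="",
        lnL_independent=fit_indep.log_likelihood,
        lnL_mutual=fit_mutual.log_likelihood,
        lr_statistic=lr,
        p_value=p,
        q_value=p,
        associated=bool(p <= alpha),
    )


def _char_seed(master_seed: int, run: int, character_id: str) -> int:
    """Per-(run, character) seed independent of character ordering."""
    digest = hashlib.sha256(
        f"{master_seed}|{run}|{character_id}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def fit_lrt_pair(
    tl: TreeLikelihood | PhyloTree,
    tips: np.ndarray,
    seed: int = 0,
    n_restarts: int = 1,
    bounds=DEFAULT_BOUNDS,
    maxiter: int = 500,
    root_prior=None,
) -> tuple[FitResult, FitResult]:
    """Fit the independent model, then the mutual model warm-started from
    the independent solution (guaranteeing LRT >= 0) plus random restarts."""
    tl = tl if isinstance(tl, TreeLikelihood) else TreeLikelihood(tl)
    det_init = np.full(8, 2.0 / max(tl.mean_depth, 1e-6))
    fit_i = fit_ml(
        tl, tips, "independent", n_restarts=n_restarts, seed=seed,
        bounds=bounds, maxiter=maxiter, init_rates=[det_init],
        root_prior=root_prior,
    )
    fit_m = fit_ml(
        tl, tips, "mutual", n_restarts=n_restarts, seed=seed + 1,
        bounds=bounds, maxiter=maxiter,
        init_rates=[fit_i.rates.as_array()], root_prior=root_prior,
    )
    # polish the null fit from the alternative's solution projected onto the
    # independence constraints; can only raise lnL_indep, tightening the LRT
    refit = fit_ml(
        tl, tips, "independent", n_restarts=0, seed=seed,
        bounds=bounds, maxiter=maxiter,
        init_rates=[fit_m.rates.as_array()], root_prior=root_prior,
    )
    if refit.log_likelihood > fit_i.log_likelihood:
        fit_i = refit
    return fit_i, fit_m


def consensus_scan(
    tree: PhyloTree | TreeLikelihood,
    matrix: CharacterMatrix,
    focal_character: str,
    n_runs: int = 100,
    agree_threshold: int = 90,
    fdr: float = 0.05,
    seed: int = 0,
    n_restarts: int = 1,
    bounds=DEFAULT_BOUNDS,
    maxiter: int = 500,
) -> list[AssociationResult]:
    """Replicate-consensus association screen of all characters against the
    focal one.

    Each run refits every character with its own optimizer restarts and
    flags characters by BH-corrected LRT p-value at ``fdr``; a character is
    associated iff flagged in >= ``agree_threshold`` of ``n_runs`` runs.
    Per-(run, character) seeds derive from ``seed`` only, so the associated
    set does not depend on character ordering. Returns one consensus
    :class:`AssociationResult` per character (medians of the per-run LRT
    quantities), sorted by character id.
    """
    if focal_character not in matrix.characters:
        raise ValidationError(
            f"focal character {focal_character!r} not in the matrix"
        )
    if n_runs < agree_threshold:
        raise ValidationError("agree_threshold cannot exceed n_runs")
    tl = tree if isinstance(tree, TreeLikelihood) else TreeLikelihood(tree)
    h = matrix.states.loc[tl.leaf_labels, focal_character].to_numpy(np.int64)
    chars = sorted(c for c in matrix.characters if c != focal_character)
    tips_by_char = {
        c: joint_states(h, matrix.states.loc[tl.leaf_labels, c].to_numpy(np.int64))
        for c in chars
    }
    flagged = {c: 0 for c in chars}
    stats: dict[str, dict[str, list[float]]] = {
        c: {"lnL_i": [], "lnL_m": [], "lr": [], "p": [], "q": []} for c in chars
    }
    for run in range(n_runs):
        pvals = []
        for c in chars:
            fit_i, fit_m = fit_lrt_pair(
                tl, tips_by_char[c], seed=_char_seed(seed, run, c),
                n_restarts=n_restarts, bounds=bounds, maxiter=maxiter,
            )
            res = lrt_association(fit_i, fit_m)
            stats[c]["lnL_i"].append(res.lnL_independent)
            stats[c]["lnL_m"].append(res.lnL_mutual)
            stats[c]["lr"].append(res.lr_statistic)
            pvals.append(res.p_value)
        reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for c, p, q, rej in zip(chars, pvals, qvals, reject):
            stats[c]["p"].append(float(p))
            stats[c]["q"].append(float(q))
            if rej:
                flagged[c] += 1
    out = []
    for c in chars:
        s = stats[c]
        out.append(
            AssociationResult(
                character_id=c,
                lnL_independent=float(np.median(s["lnL_i"])),
                lnL_mutual=float(np.median(s["lnL_m"])),
                lr_statistic=float(np.median(s["lr"])),
                p_value=float(np.median(s["p"])),
                q_value=float(np.median(s["q"])),
                associated=bool(flagged[c] >= agree_threshold),
                n_runs_flagged=flagged[c],
                n_runs=n_runs,
            )
        )
    return out


def select_best_model(aics: dict[str, float]) -> str:
    """AIC winner with deterministic tie-breaking toward fewer parameters
    (then the fixed model order independent, partner_follows_focal,
    focal_follows_partner, mutual)."""
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    return min(aics, key=lambda m: (aics[m], order[m]))


def classify_model(
    tree: PhyloTree | TreeLikelihood,
    tips: np.ndarray,
    n_runs: int = 100,
    agree_threshold: int = 90,
    seed: int = 0,
    character_id: str = "",
    n_restarts: int = 1,
    bounds=DEFAULT_BOUNDS,
    maxiter: int = 500,
) -> ClassificationResult:
    """Consensus AIC classification of one character into the four models.

    Per run, the independent model is fitted first and the three dependency
    models are warm-started from its solution (they nest it), each with its
    own random restarts; the per-run winner minimizes AIC. The character is
    ``classified`` only if the modal model wins in >= ``agree_threshold``
    runs. The returned ``fits`` hold, per model, the best fit seen across
    runs; ``mutual_rates_per_run`` preserves each run's mutual-model rates
    for downstream client scoring.
    """
    if n_runs < agree_threshold:
        raise ValidationError("agree_threshold cannot exceed n_runs")
    tl = tree if isinstance(tree, TreeLikelihood) else TreeLikelihood(tree)
    tips = np.asarray(tips, dtype=np.int64)
    det_init = np.full(8, 2.0 / max(tl.mean_depth, 1e-6))
    votes = {m: 0 for m in MODEL_ORDER}
    best_fits: dict[str, FitResult] = {}
    mutual_rates: list[RateParameters] = []
    for run in range(n_runs):
        run_seed = _char_seed(seed, run, character_id or "<anon>")
        fit_i = fit_ml(
            tl, tips, "independent", n_restarts=n_restarts, seed=run_seed,
            bounds=bounds, maxiter=maxiter, init_rates=[det_init],
        )
        fits = {"independent": fit_i}
        for j, name in enumerate(
            ("partner_follows_focal", "focal_follows_partner", "mutual")
        ):
            fits[name] = fit_ml(
                tl, tips, name, n_restarts=n_restarts, seed=run_seed + j + 1,
                bounds=bounds, maxiter=maxiter,
                init_rates=[fit_i.rates.as_array()],
            )
        winner = select_best_model({m: f.aic for m, f in fits.items()})
        votes[winner] += 1
        mutual_rates.append(fits["mutual"].rates)
        for m, f in fits.items():
            if m not in best_fits or f.log_likelihood > best_fits[m].log_likelihood:
                best_fits[m] = f
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    best_model = max(votes, key=lambda m: (votes[m], -order[m]))
    return ClassificationResult(
        character_id=character_id,
        fits=best_fits,
        best_model=best_model,
        consensus_count=votes[best_model],
        n_runs=n_runs,
        classified=bool(votes[best_model] >= agree_threshold),
        votes=votes,
        mutual_rates_per_run=mutual_rates,
    )
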