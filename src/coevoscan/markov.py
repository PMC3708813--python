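"""The 4-state Markov model of two co-evolving binary characters.

Two binary characters — a focal character *h* (e.g. the chaperone gene
*hsp90A*/*htpG*) and a partner character *X* (another gene, or an organismal
trait) — evolve jointly along a rooted phylogeny as a continuous-time Markov
chain over the four joint states

====  ==========  =====================
idx   label       (h, X)
====  ==========  =====================
0     1 / A       (h absent, X absent)
1     2 / B       (h present, X absent)
2     3 / C       (h absent, X present)
3     4 / D       (h present, X present)
====  ==========  =====================

Only one character may change at a time, so the generator has exactly eight
free off-diagonal entries, ``q12, q13, q21, q31, q24, q34, q42, q43``
(``qxy`` = rate from joint state x to joint state y in 1-based labels).
Equality restrictions on these rates define four nested dependency models:

- ``independent``:          q12=q34, q21=q43, q13=q24, q31=q42 (4 free) —
  each character gains/loses at rates blind to the other's state;
- ``mutual``:               no restrictions (8 free);
- ``partner_follows_focal``: q12=q34, q21=q43 (6 free) — X's dynamics depend
  on h, but h evolves independently of X;
- ``focal_follows_partner``: q13=q24, q31=q42 (6 free) — the converse.

Likelihoods of tip data are computed with Felsenstein's pruning algorithm;
rates are estimated by bounded maximum likelihood in log-rate space with
random restarts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from ._pruning import prune, prune_eig
from .data import PhyloTree
from .errors import ValidationError

RATE_NAMES = ("q12", "q13", "q21", "q31", "q24", "q34", "q42", "q43")

#: (row, col) generator slot of each named rate, 0-based joint-state indices.
_RATE_SLOTS = ((0, 1), (0, 2), (1, 0), (2, 0), (1, 3), (2, 3), (3, 1), (3, 2))

STATE_LABELS = ("(h-,X-)", "(h+,X-)", "(h-,X+)", "(h+,X+)")

DEFAULT_BOUNDS = (1e-8, 100.0)
DEFAULT_RESTARTS = 10


@dataclass(frozen=True)
class RateParameters:
    """The eight single-character transition rates (events per unit branch
    length) of the joint model."""

    q12: float
    q13: float
    q21: float
    q31: float
    q24: float
    q34: float
    q42: float
    q43: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "RateParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (8,):
            raise ValidationError("expected 8 rates")
        return cls(**dict(zip(RATE_NAMES, values.tolist())))

    def validate(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValidationError(f"rates must be finite and >= 0, got {arr}")


@dataclass(frozen=True)
class ModelSpec:
    """One of the four dependency models, as a tying of the eight rates.

    ``tie_index[i]`` gives, for rate slot ``RATE_NAMES[i]``, the index of the
    free parameter it is tied to; ``free_names`` names the free parameters.
    """

    name: str
    tie_index: tuple[int, ...]
    free_names: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def expand(self, free: np.ndarray) -> np.ndarray:
        """Free parameter vector -> full 8-rate vector."""
        return np.asarray(free, dtype=float)[list(self.tie_index)]

    def reduce(self, rates: np.ndarray) -> np.ndarray:
        """Full 8-rate vector -> free parameters.

        Tied slots are combined by their geometric mean (the natural
        projection in log-rate space); exact when the rates already satisfy
        the model's equalities.
        """
        rates = np.asarray(rates, dtype=float)
        logs = np.log(np.maximum(rates, 1e-300))
        sums = np.zeros(self.n_free)
        counts = np.zeros(self.n_free)
        for slot, f in enumerate(self.tie_index):
            sums[f] += logs[slot]
            counts[f] += 1
        return np.exp(sums / counts)

    def satisfied_by(self, rates: np.ndarray, rtol: float = 1e-6) -> bool:
        rates = np.asarray(rates, dtype=float)
        return bool(np.allclose(rates, self.expand(self.reduce(rates)), rtol=rtol))


MODELS: dict[str, ModelSpec] = {
    "independent": ModelSpec(
        "independent",
        tie_index=(0, 2, 1, 3, 2, 0, 3, 1),
        free_names=("h_gain", "h_loss", "x_gain", "x_loss"),
    ),
    "mutual": ModelSpec("mutual", tie_index=tuple(range(8)), free_names=RATE_NAMES),
    "partner_follows_focal": ModelSpec(
        "partner_follows_focal",
        tie_index=(0, 2, 1, 3, 4, 0, 5, 1),
        free_names=("h_gain", "h_loss", "q13", "q31", "q24", "q42"),
    ),
    "focal_follows_partner": ModelSpec(
        "focal_follows_partner",
        tie_index=(0, 1, 2, 3, 1, 4, 3, 5),
        free_names=("q12", "x_gain", "q21", "x_loss", "q34", "q43"),
    ),
}

#: Order used for deterministic tie-breaking (fewest parameters first).
MODEL_ORDER = ("independent", "partner_follows_focal", "focal_follows_partner", "mutual")


def resolve_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValidationError(
            f"unknown model {model!r}; expected one of {sorted(MODELS)}"
        ) from None


def count_free_params(model: str | ModelSpec) -> int:
    """Free rate parameters of a dependency model (4, 8, 6 or 6)."""
    return resolve_model(model).n_free


def build_generator(
    rates: RateParameters | np.ndarray, model: str | ModelSpec | None = None
) -> np.ndarray:
    """Assemble the 4×4 generator from the eight rates.

    Forbidden double transitions (1↔4, 2↔3) are exactly zero and the diagonal
    is the negative row sum. When ``model`` is given, the rates are checked
    against the model's equality restrictions.
    """
    if isinstance(rates, RateParameters):
        rates.validate()
        arr = rates.as_array()
    else:
        arr = np.asarray(rates, dtype=float)
        if arr.shape != (8,):
            raise ValidationError("expected 8 rates")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValidationError(f"rates must be finite and >= 0, got {arr}")
    if model is not None:
        spec = resolve_model(model)
        if not spec.satisfied_by(arr):
            raise ValidationError(
                f"rates do not satisfy the {spec.name!r} model's restrictions"
            )
    Q = np.zeros((4, 4))
    for (i, j), q in zip(_RATE_SLOTS, arr):
        Q[i, j] = q
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def rates_from_generator(Q: np.ndarray) -> RateParameters:
    return RateParameters.from_array([Q[i, j] for i, j in _RATE_SLOTS])


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix exp(Q·t) for one branch duration ``t >= 0``."""
    if t < 0:
        raise ValidationError("t must be >= 0")
    return scipy.linalg.expm(np.asarray(Q, dtype=float) * t)


def _expm_edges(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q·t) for every edge duration at once.

    Fast path: eigendecomposition of the 4×4 generator, shared across all
    edges. Falls back to scipy's expm per unique duration when the
    eigenvector matrix is ill-conditioned (defective generators arise at
    exact rate ties).
    """
    w, V = np.linalg.eig(Q)
    ok = False
    if np.all(np.isfinite(w)) and np.all(np.isfinite(V)):
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:  # pragma: no cover
            Vinv = None
        # cheap 1-norm condition estimate; defective V has a huge inverse
        if Vinv is not None and (
            np.abs(V).max() * np.abs(Vinv).max() < 1e9
        ):
            E = np.exp(lengths[:, None] * w[None, :])
            P = ((V[None, :, :] * E[:, None, :]) @ Vinv).real
            # eigen round-off: clip tiny negatives, verify stochasticity
            np.clip(P, 0.0, None, out=P)
            rowsum = P.sum(axis=2)
            if np.max(np.abs(rowsum - 1.0)) < 1e-8:
                ok = True
    if not ok:  # pragma: no cover - rare degenerate generators
        uniq, inv = np.unique(lengths, return_inverse=True)
        mats = np.stack([scipy.linalg.expm(Q * t) for t in uniq])
        P = mats[inv]
        np.clip(P, 0.0, None, out=P)
    return P


def joint_states(h_states: np.ndarray, x_states: np.ndarray) -> np.ndarray:
    """Map paired binary tip states to joint state indices 0..3
    (index = h + 2·X)."""
    h = np.asarray(h_states, dtype=np.int64)
    x = np.asarray(x_states, dtype=np.int64)
    if h.shape != x.shape:
        raise ValidationError("paired state vectors differ in length")
    if not (np.isin(h, (0, 1)).all() and np.isin(x, (0, 1)).all()):
        raise ValidationError("tip states must be binary")
    return h + 2 * x


class TreeLikelihood:
    """Pruning-algorithm likelihood evaluator, compiled once per tree.

    The tree topology and branch lengths are flattened to arrays so that
    repeated likelihood evaluations during optimisation only pay for the
    per-edge matrix exponentials and the post-order sweep.
    """

    def __init__(self, tree: PhyloTree):
        nodes = list(tree.tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.order = np.arange(self.n_nodes, dtype=np.int64)  # postorder
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.edge_lengths = np.zeros(self.n_nodes)
        self.leaf_index: dict[str, int] = {}
        is_leaf = np.zeros(self.n_nodes, dtype=bool)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                self.edge_lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                is_leaf[i] = True
                self.leaf_index[nd.taxon.label] = i
        self.is_leaf = is_leaf
        self.leaf_labels = [l.taxon.label for l in tree.tree.leaf_node_iter()]
        depth = np.zeros(self.n_nodes)
        for i in self.order[::-1]:  # preorder: parents before children
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.edge_lengths[i]
        #: mean root-to-tip path length; a natural time scale for rate guesses
        self.mean_depth = float(depth[is_leaf].mean())

    def tip_partials(self, joint: np.ndarray) -> np.ndarray:
        """Base partial-likelihood array for one joint tip-state vector,
        aligned with this tree's leaf order."""
        joint = np.asarray(joint, dtype=np.int64)
        if joint.shape != (len(self.leaf_labels),):
            raise ValidationError(
                f"expected {len(self.leaf_labels)} tip states, got {joint.shape}"
            )
        partials = np.ones((self.n_nodes, 4))
        for label, state in zip(self.leaf_labels, joint):
            i = self.leaf_index[label]
            partials[i] = 0.0
            partials[i, state] = 1.0
        return partials

    def loglik(
        self,
        base_partials: np.ndarray,
        rates8: np.ndarray,
        root_prior: np.ndarray,
    ) -> float:
        Q = np.zeros((4, 4))
        for (i, j), q in zip(_RATE_SLOTS, rates8):
            Q[i, j] = q
        np.fill_diagonal(Q, -Q.sum(axis=1))
        if prune_eig is not None:
            w, V = np.linalg.eig(Q)
            if np.all(np.isfinite(w)) and np.all(np.isfinite(V)):
                try:
                    Vinv = np.linalg.inv(V)
                except np.linalg.LinAlgError:  # pragma: no cover
                    Vinv = None
                if Vinv is not None and np.abs(V).max() * np.abs(Vinv).max() < 1e9:
                    # spot-check stochasticity on the longest edge before
                    # trusting the eigen route (defective Q fails here)
                    tmax = self.edge_lengths.max()
                    Ptest = ((V * np.exp(w * tmax)[None, :]) @ Vinv).real
                    if np.max(np.abs(Ptest.sum(axis=1) - 1.0)) < 1e-8:
                        return float(
                            prune_eig(
                                self.order,
                                self.parent,
                                self.edge_lengths,
                                w.astype(np.complex128),
                                V.astype(np.complex128),
                                Vinv.astype(np.complex128),
                                base_partials.copy(),
                                root_prior,
                            )
                        )
        P = _expm_edges(Q, self.edge_lengths)
        return float(
            prune(self.order, self.parent, P, base_partials.copy(), root_prior)
        )


def _resolve_prior(root_prior, rates8: np.ndarray | None = None) -> np.ndarray:
    if root_prior is None or (
        isinstance(root_prior, str) and root_prior == "uniform"
    ):
        return np.full(4, 0.25)
    if isinstance(root_prior, str) and root_prior == "stationary":
        from .clients import steady_state  # local import to avoid a cycle

        return steady_state(build_generator(rates8)).as_array()
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (4,) or abs(prior.sum() - 1.0) > 1e-8 or np.any(prior < 0):
        raise ValidationError("root_prior must be a length-4 distribution")
    return prior


def log_likelihood(
    tree: PhyloTree | TreeLikelihood,
    tips: np.ndarray,
    rates: RateParameters | np.ndarray,
    model: str | ModelSpec | None = None,
    root_prior=None,
) -> float:
    """Log pruning likelihood of joint tip states under given rates.

    ``tips`` is a vector of joint state indices 0..3 in the tree's leaf
    order (use :func:`joint_states` to build it from two binary vectors).
    """
    tl = tree if isinstance(tree, TreeLikelihood) else TreeLikelihood(tree)
    arr = rates.as_array() if isinstance(rates, RateParameters) else np.asarray(rates)
    if model is not None:
        build_generator(arr, model)  # validates restrictions
    prior = _resolve_prior(root_prior, arr)
    return tl.loglik(tl.tip_partials(tips), arr, prior)


def data_fingerprint(tl: TreeLikelihood, tips: np.ndarray) -> str:
    """Stable hash of (tree shape, branch lengths, tip states) used to refuse
    comparisons of fits made on different data."""
    h = hashlib.sha256()
    h.update(np.asarray(tips, dtype=np.int64).tobytes())
    h.update(tl.edge_lengths.tobytes())
    h.update(tl.parent.tobytes())
    h.update("|".join(tl.leaf_labels).encode())
    return h.hexdigest()[:16]


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: ModelSpec
    rates: RateParameters
    log_likelihood: float
    aic: float
    n_restarts: int
    converged: bool
    seed: int | None
    data_hash: str = ""
    diagnostics: dict = field(default_factory=dict)


def fit_ml(
    tree: PhyloTree | TreeLikelihood,
    tips: np.ndarray,
    model: str | ModelSpec = "mutual",
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int | None = 0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    root_prior=None,
    init_rates=None,
    maxiter: int = 500,
) -> FitResult:
    """Best-of-restarts bounded ML estimation of a model's free rates.

    Optimisation runs in log-rate space within ``bounds`` (default
    [1e-8, 100] per rate) with L-BFGS-B. Starting points are ``init_rates``
    (full 8-rate vectors, e.g. a nested model's solution used as a warm
    start) followed by ``n_restarts`` log-uniform random draws within the
    bounds, seeded — the whole fit is deterministic given ``seed``. Ties in
    final log-likelihood keep the earliest restart. If no restart converges
    the best evaluated point is still returned with ``converged=False``.
    """
    spec = resolve_model(model)
    if n_restarts < 1 and not init_rates:
        raise ValidationError("need n_restarts >= 1 or explicit init_rates")
    tl = tree if isinstance(tree, TreeLikelihood) else TreeLikelihood(tree)
    tips = np.asarray(tips, dtype=np.int64)
    base = tl.tip_partials(tips)
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValidationError("bounds must satisfy 0 < lo < hi")
    llo, lhi = np.log(lo), np.log(hi)
    k = spec.n_free
    fixed_prior = None
    if not (isinstance(root_prior, str) and root_prior == "stationary"):
        fixed_prior = _resolve_prior(root_prior)

    def negll(x: np.ndarray) -> float:
        rates8 = spec.expand(np.exp(x))
        prior = fixed_prior
        if prior is None:
            prior = _resolve_prior("stationary", rates8)
        ll = tl.loglik(base, rates8, prior)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    starts: list[np.ndarray] = []
    if init_rates is not None:
        for r in init_rates:
            arr = r.as_array() if isinstance(r, RateParameters) else np.asarray(r)
            starts.append(np.log(np.clip(spec.reduce(arr), lo, hi)))
    rng = np.random.default_rng(seed)
    if n_restarts > 0:
        starts.extend(rng.uniform(llo, lhi, size=(n_restarts, k)))

    best = None
    best_ll = -np.inf
    any_success = False
    for x0 in starts:
        res = scipy.optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=[(llo, lhi)] * k,
            options={"maxiter": maxiter},
        )
        any_success = any_success or bool(res.success)
        ll = -float(res.fun)
        if best is None or ll > best_ll:
            best, best_ll = res, ll
    rates8 = spec.expand(np.exp(best.x))
    return FitResult(
        model=spec,
        rates=RateParameters.from_array(rates8),
        log_likelihood=best_ll,
        aic=2.0 * k - 2.0 * best_ll,
        n_restarts=len(starts),
        converged=any_success,
        seed=seed,
        data_hash=data_fingerprint(tl, tips),
        diagnostics={"message": str(best.message), "nit": int(best.nit)},
    )
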