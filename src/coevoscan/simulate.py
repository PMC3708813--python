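"""Truth-labelled synthetic data for the co-evolution screen.

Generates birth–death trees and paired binary characters evolved under any
of the four dependency models by exact stochastic simulation of the 4-state
chain (Gillespie along each branch), and assembles screen-scale datasets:
one focal character (the *hsp90A* stand-in) plus a mix of partner genes
with known generating models and rates, so every pipeline stage can be
validated against ground truth without external databases.

Default simulation conditions (documented in docs/methods.md): Yule trees
(birth 1, death 0, height ≈ ln n), background genes gained and lost at rate
0.5 each, dependent genes with 10-fold rate contrasts between focal-present
and focal-absent backgrounds, and client-like genes whose gain without the
focal character is 100-fold slower than their loss.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .data import CharacterMatrix, PhyloTree
from .errors import ValidationError
from .markov import (
    ModelSpec,
    RateParameters,
    build_generator,
    resolve_model,
)
from .clients import regularize_rates, steady_state

DEFAULT_FOCAL_ID = "hsp90A"

#: Background (independent) gene: gain = loss = 0.5 for both characters.
INDEPENDENT_RATES = RateParameters(
    q12=0.5, q13=0.5, q21=0.5, q31=0.5, q24=0.5, q34=0.5, q42=0.5, q43=0.5
)

#: Partner follows focal, positive association with a 10-fold contrast:
#: gained fast / lost slowly when the focal gene is present, the reverse
#: when it is absent. Focal rates stay at 0.5.
PARTNER_FOLLOWS_FOCAL_RATES = RateParameters(
    q12=0.5, q34=0.5, q21=0.5, q43=0.5,  # focal unaffected by partner
    q13=0.1, q31=1.0,                    # partner without focal: rare, short-lived
    q24=1.0, q42=0.1,                    # partner with focal: common, stable
)

#: Mirror image: the focal gene follows the partner.
FOCAL_FOLLOWS_PARTNER_RATES = RateParameters(
    q13=0.5, q24=0.5, q31=0.5, q42=0.5,  # partner unaffected by focal
    q12=0.1, q21=1.0,
    q34=1.0, q43=0.1,
)

#: Mutual dependence: both 10-fold contrasts at once.
MUTUAL_RATES = RateParameters(
    q12=0.1, q21=1.0, q34=1.0, q43=0.1,
    q13=0.1, q31=1.0, q24=1.0, q42=0.1,
)

#: Client-like partner: essentially never present without the focal gene
#: (tiny q13, large q31) but well-behaved alongside it.
CLIENT_RATES = RateParameters(
    q12=0.5, q34=0.5, q21=0.5, q43=0.5,
    q13=0.01, q31=1.0,
    q24=1.0, q42=0.1,
)

DEFAULT_RATES_BY_MODEL = {
    "independent": INDEPENDENT_RATES,
    "partner_follows_focal": PARTNER_FOLLOWS_FOCAL_RATES,
    "focal_follows_partner": FOCAL_FOLLOWS_PARTNER_RATES,
    "mutual": MUTUAL_RATES,
}


def simulate_tree(
    n_taxa: int, birth: float = 1.0, death: float = 0.0, seed: int = 0
) -> PhyloTree:
    """Simulate an ultrametric birth–death tree with ``n_taxa`` extant tips.

    Deterministic given ``seed``. Requires ``birth > death >= 0`` and
    ``n_taxa >= 3``.
    """
    if n_taxa < 3:
        raise ValidationError("n_taxa must be >= 3")
    if not (birth > death >= 0):
        raise ValidationError("need birth > death >= 0")
    tree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length or 0.0) <= 0.0:
            node.edge.length = 1e-8
    out = PhyloTree(tree)
    out.validate()
    return out


def _gillespie_edge(
    Q: np.ndarray, state: int, duration: float, rng: np.random.Generator
) -> tuple[int, list[tuple[int, float]]]:
    """Evolve one lineage for ``duration``; returns the end state and the
    piecewise-constant path [(state, dwell time), ...]."""
    path: list[tuple[int, float]] = []
    t = 0.0
    while True:
        exit_rate = -Q[state, state]
        if exit_rate <= 0.0:
            path.append((state, duration - t))
            return state, path
        wait = rng.exponential(1.0 / exit_rate)
        if t + wait >= duration:
            path.append((state, duration - t))
            return state, path
        path.append((state, wait))
        t += wait
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(4, p=probs))


def _draw_root_state(
    Q: np.ndarray, rates8: np.ndarray, rng: np.random.Generator
) -> int:
    pi = steady_state(build_generator(regularize_rates(rates8))).as_array()
    return int(rng.choice(4, p=pi))


def simulate_pair(
    tree: PhyloTree,
    rates: RateParameters | np.ndarray,
    model: str | ModelSpec | None = None,
    root_state: int | None = None,
    seed: int = 0,
    return_paths: bool = False,
):
    """Exact realization of the joint 4-state chain along the tree.

    Along each branch, exponential waiting times are drawn from the current
    state's total exit rate and jumps follow the generator rows — no
    discretisation. Returns the joint tip states (indices 0..3) in the
    tree's leaf order; with ``return_paths`` also the per-edge state paths
    keyed by leaf-set-free node ids (used by the conditional simulation
    mode). The root state is drawn from the (regularized) stationary
    distribution unless given.
    """
    arr = rates.as_array() if isinstance(rates, RateParameters) else np.asarray(
        rates, dtype=float
    )
    if model is not None:
        spec = resolve_model(model)
        if not spec.satisfied_by(arr):
            raise ValidationError(
                f"rates do not satisfy the {spec.name!r} model's restrictions"
            )
    Q = build_generator(arr)
    rng = np.random.default_rng(seed)
    if root_state is None:
        if not np.any(arr > 0):
            raise ValidationError(
                "all rates are zero: supply an explicit root_state"
            )
        root_state = _draw_root_state(Q, arr, rng)
    if root_state not in (0, 1, 2, 3):
        raise ValidationError("root_state must be in {0,1,2,3}")

    states: dict[int, int] = {}
    paths: dict[int, list[tuple[int, float]]] = {}
    nodes = list(tree.tree.preorder_node_iter())
    states[id(nodes[0])] = root_state
    for node in nodes:
        if node.parent_node is None:
            continue
        start = states[id(node.parent_node)]
        end, path = _gillespie_edge(Q, start, float(node.edge.length), rng)
        states[id(node)] = end
        paths[id(node)] = path
    tips = np.array(
        [states[id(leaf)] for leaf in tree.tree.leaf_node_iter()], dtype=np.int64
    )
    if return_paths:
        return tips, paths
    return tips


def _simulate_partner_given_focal_path(
    tree: PhyloTree,
    focal_paths: dict[int, list[tuple[int, float]]],
    focal_root: int,
    rates8: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partner states conditional on a recorded focal path.

    The partner evolves as a 2-state chain whose gain/loss rates switch with
    the focal state along each edge (Markov-modulated simulation). This is
    exact when the focal character's own rates do not depend on the partner
    (independent and partner_follows_focal models) and an approximation
    otherwise.
    """
    q12, q13, q21, q31, q24, q34, q42, q43 = rates8
    # partner gain/loss given focal state: focal absent -> (q13, q31),
    # focal present -> (q24, q42)
    gain = {0: q13, 1: q24}
    loss = {0: q31, 1: q42}
    # partner root state from its stationary distribution given focal root
    h0 = focal_root % 2
    g, l = gain[h0], loss[h0]
    p1 = g / (g + l) if g + l > 0 else 0.0
    x_states: dict[int, int] = {}
    nodes = list(tree.tree.preorder_node_iter())
    x_states[id(nodes[0])] = int(rng.random() < p1)
    for node in nodes:
        if node.parent_node is None:
            continue
        x = x_states[id(node.parent_node)]
        for h_state, dwell in focal_paths[id(node)]:
            h = h_state % 2
            t = 0.0
            while True:
                rate = loss[h] if x else gain[h]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if t + wait >= dwell:
                    break
                t += wait
                x = 1 - x
        x_states[id(node)] = x
    return np.array(
        [x_states[id(leaf)] for leaf in tree.tree.leaf_node_iter()], dtype=np.int64
    )


@dataclass
class SimulationSpec:
    """Recipe for a truth-labelled screen dataset.

    ``genes`` lists (model_name, rates, n_genes) blocks; each simulated gene
    records its generating model and rates in the truth table. When ``tree``
    is None a birth–death tree is simulated from ``n_taxa``/``birth``/
    ``death``.

    ``shared_focal`` (default True) conditions every partner gene on one
    recorded focal realization — the matrix's focal column — so the
    correlations the screen is meant to detect are actually present in the
    dataset. Markov-modulated conditional simulation is exact whenever the
    focal character's own rates do not depend on the partner (independent
    and partner-follows-focal blocks, including client-like genes) and
    realizes only the partner-direction dependence otherwise. With
    ``shared_focal=False`` each gene instead gets a fresh exact joint
    realization whose focal copy is discarded: marginally correct per gene,
    but the shared focal column is then independent of every partner column
    (use :func:`simulate_pair` directly for per-gene fitting studies).
    """

    genes: list[tuple[str, RateParameters, int]]
    tree: PhyloTree | None = None
    n_taxa: int = 150
    birth: float = 1.0
    death: float = 0.0
    focal_gain: float = 0.5
    focal_loss: float = 0.5
    focal_id: str = DEFAULT_FOCAL_ID
    min_present: int = 5
    min_absent: int = 5
    max_retries: int = 20
    shared_focal: bool = True
    seed: int = 0


def default_screen_spec(
    n_independent: int = 40,
    n_mutual: int = 0,
    n_partner_follows_focal: int = 0,
    n_focal_follows_partner: int = 0,
    n_client: int = 0,
    **kwargs,
) -> SimulationSpec:
    """Convenience builder using the package's default per-model rates;
    client-like genes are labelled ``partner_follows_focal`` (their true
    model class) with :data:`CLIENT_RATES`."""
    genes: list[tuple[str, RateParameters, int]] = []
    if n_independent:
        genes.append(("independent", INDEPENDENT_RATES, n_independent))
    if n_mutual:
        genes.append(("mutual", MUTUAL_RATES, n_mutual))
    if n_partner_follows_focal:
        genes.append(
            ("partner_follows_focal", PARTNER_FOLLOWS_FOCAL_RATES,
             n_partner_follows_focal)
        )
    if n_focal_follows_partner:
        genes.append(
            ("focal_follows_partner", FOCAL_FOLLOWS_PARTNER_RATES,
             n_focal_follows_partner)
        )
    if n_client:
        genes.append(("partner_follows_focal", CLIENT_RATES, n_client))
    return SimulationSpec(genes=genes, **kwargs)


def make_screen_dataset(
    spec: SimulationSpec,
) -> tuple[PhyloTree, CharacterMatrix, pd.DataFrame]:
    """Simulate a full screen dataset from a :class:`SimulationSpec`.

    Returns the tree, a character matrix whose first column is the focal
    character, and a truth table (one row per partner gene: generating
    model, the eight rates, and how many regenerations the presence/absence
    filter forced). Characters failing the min_present/min_absent filter
    are re-simulated up to ``max_retries`` times.
    """
    ss = np.random.SeedSequence(spec.seed)
    tree_seed, focal_seed, genes_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    tree = spec.tree or simulate_tree(spec.n_taxa, spec.birth, spec.death, tree_seed)
    n = tree.n_leaves

    # independent-tied rate vector whose h marginal is a clean 2-state
    # (focal_gain, focal_loss) process; the partner slots are dummies
    focal_rates8 = np.array(
        [spec.focal_gain, 0.5, spec.focal_loss, 0.5,
         0.5, spec.focal_gain, 0.5, spec.focal_loss]
    )

    def passes(v: np.ndarray) -> bool:
        ones = int(v.sum())
        return ones >= spec.min_present and (n - ones) >= spec.min_absent

    # Designated focal realization (retried until it passes the filter).
    focal_rng_seeds = np.random.SeedSequence(focal_seed).spawn(spec.max_retries + 1)
    focal_h = None
    focal_paths = None
    for s in focal_rng_seeds:
        sd = int(s.generate_state(1)[0] % (2**31))
        tips, paths = simulate_pair(
            tree, focal_rates8, model=None, seed=sd, return_paths=True
        )
        h = tips % 2
        if passes(h):
            focal_h, focal_paths = h, paths
            focal_root = _root_state_from_paths(tree, paths, tips)
            break
    if focal_h is None:
        raise ValidationError(
            "focal character failed the presence/absence filter in "
            f"{spec.max_retries + 1} attempts; adjust focal gain/loss rates"
        )

    columns: dict[str, np.ndarray] = {spec.focal_id: focal_h}
    truth_rows = []
    gene_counter = 0
    gene_ss = np.random.SeedSequence(genes_seed)
    total_genes = sum(ng for _, _, ng in spec.genes)
    gene_seeds = gene_ss.spawn(total_genes)
    idx = 0
    for model_name, rates, n_genes in spec.genes:
        spec_model = resolve_model(model_name)
        arr = rates.as_array()
        if not spec_model.satisfied_by(arr):
            raise ValidationError(
                f"rates for block {model_name!r} violate its restrictions"
            )
        for _ in range(n_genes):
            gene_counter += 1
            gid = f"gene_{gene_counter:04d}"
            retry_ss = gene_seeds[idx].spawn(spec.max_retries + 1)
            idx += 1
            x = None
            n_regen = 0
            for attempt, s in enumerate(retry_ss):
                sd = int(s.generate_state(1)[0] % (2**31))
                if spec.shared_focal:
                    rng = np.random.default_rng(sd)
                    cand = _simulate_partner_given_focal_path(
                        tree, focal_paths, focal_root, arr, rng
                    )
                else:
                    tips = simulate_pair(tree, arr, seed=sd)
                    cand = tips // 2
                if passes(cand):
                    x = cand
                    n_regen = attempt
                    break
            if x is None:
                raise ValidationError(
                    f"gene {gid} ({model_name}) failed the presence/absence "
                    f"filter {spec.max_retries + 1} times; adjust its rates"
                )
            columns[gid] = x
            truth_rows.append(
                {"gene": gid, "model": model_name, "n_regenerated": n_regen,
                 **dict(zip(("q12", "q13", "q21", "q31", "q24", "q34",
                             "q42", "q43"), arr.tolist()))}
            )
    matrix = CharacterMatrix(
        pd.DataFrame(columns, index=pd.Index(tree.taxon_labels, name="taxon"))
    )
    matrix.validate()
    truth = pd.DataFrame(truth_rows).set_index("gene") if truth_rows else (
        pd.DataFrame(columns=["model", "n_regenerated"])
    )
    return tree, matrix, truth


def _root_state_from_paths(tree, paths, tips) -> int:
    """Root joint state implied by the recorded per-edge paths."""
    root = next(tree.tree.preorder_node_iter())
    for child in root.child_nodes():
        return paths[id(child)][0][0]
    raise ValidationError("tree has no edges")  # pragma: no cover
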