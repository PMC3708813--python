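"""End-to-end orchestration: filter → screen → classify → PCI → enrichment.

:func:`run_gene_screen` drives the full gene-mode analysis from file inputs
to a result directory of plain TSVs; :func:`run_trait_screen` runs the
per-trait variant (prune to annotated taxa, LRT, classification, gain/loss
rate table). Every run serializes its :class:`RunConfig` verbatim into the
output directory and logs per-stage counts, so results are reproducible
from the directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as dm
from .clients import pci_from_rates, rank_clients
from .enrich import hypergeom_enrichment
from .errors import CoevoscanError, InsufficientDataError, ValidationError
from .markov import RATE_NAMES, TreeLikelihood, joint_states
from .screen import classify_model, consensus_scan

logger = logging.getLogger("coevoscan")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Serializable record of everything a screen run depends on."""

    tree_path: str = ""
    matrix_path: str = ""
    traits_path: str = ""
    trait_vocab_path: str = ""  # optional YAML sidecar: trait -> {token: 0/1}
    annotations_path: str = ""
    truth_path: str = ""  # optional truth table (simulated data diagnostics)
    out_dir: str = "coevoscan_results"
    focal_character: str = "hsp90A"
    mode: str = "gene_screen"  # gene_screen | trait_screen | simulate
    epsilon: float = dm.DEFAULT_EPSILON
    min_present: int = dm.DEFAULT_MIN_PRESENT
    min_absent: int = dm.DEFAULT_MIN_ABSENT
    n_runs: int = 100
    agree_threshold: int = 90
    fdr: float = 0.05
    top_k: int = 20
    n_restarts: int = 1
    rate_bounds: tuple[float, float] = (1e-8, 100.0)
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["rate_bounds"] = list(d["rate_bounds"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "rate_bounds" in d:
            d["rate_bounds"] = tuple(d["rate_bounds"])
        return cls(**d)


def load_annotations(tsv_path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (character id, category label; one pair per
    row) into an annotation map."""
    df = pd.read_csv(tsv_path, sep="\t", header=None, names=["char", "category"],
                     dtype=str)
    out: dict[str, set[str]] = {}
    for char, cat in zip(df["char"], df["category"]):
        out.setdefault(str(char).strip(), set()).add(str(cat).strip())
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")


def _prepare(config: RunConfig):
    tree = dm.load_tree(Path(config.tree_path).read_text(), config.epsilon)
    matrix = dm.load_matrix(Path(config.matrix_path).read_text())
    tree, matrix = dm.align_tree_and_matrix(tree, matrix)
    n_before = len(matrix.characters)
    matrix, dropped = dm.filter_characters(
        matrix, config.min_present, config.min_absent
    )
    if config.focal_character not in matrix.characters:
        raise ValidationError(
            f"focal character {config.focal_character!r} missing from the "
            "matrix after filtering"
        )
    logger.info(
        "prepared inputs: %d taxa, %d/%d characters kept (%d dropped)",
        len(matrix.taxa), len(matrix.characters), n_before, len(dropped),
    )
    return tree, matrix, dropped


def run_gene_screen(config: RunConfig) -> Path:
    """Run the full gene-mode pipeline; returns the result directory.

    Writes ``associations.tsv`` (per-character LRT consensus),
    ``classifications.tsv`` (per-model AIC, rates of the winning model),
    ``pci.tsv`` (per-run-averaged client index, consensus client flag) and
    ``enrichment.tsv`` (hypergeometric over-representation of annotations
    in the associated set, when an annotation map is configured), plus the
    config and a per-stage log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        tree, matrix, dropped = _prepare(config)
        tl = TreeLikelihood(tree)

        # stage 1: association screen
        assoc = consensus_scan(
            tl, matrix, config.focal_character,
            n_runs=config.n_runs, agree_threshold=config.agree_threshold,
            fdr=config.fdr, seed=config.seed, n_restarts=config.n_restarts,
            bounds=config.rate_bounds,
        )
        assoc_df = pd.DataFrame(
            [dataclasses.asdict(a) for a in assoc]
        ).sort_values(["associated", "q_value", "character_id"],
                      ascending=[False, True, True])
        _write_tsv(assoc_df, out / "associations.tsv")
        associated = [a.character_id for a in assoc if a.associated]
        logger.info("association screen: %d/%d characters associated",
                    len(associated), len(assoc))

        # stage 2: model classification of screen survivors
        h = matrix.states.loc[tl.leaf_labels,
                              config.focal_character].to_numpy(np.int64)
        rows = []
        pci_per_run: dict[str, list[float]] = {}
        for char in associated:
            tips = joint_states(
                h, matrix.states.loc[tl.leaf_labels, char].to_numpy(np.int64)
            )
            cls = classify_model(
                tl, tips, n_runs=config.n_runs,
                agree_threshold=config.agree_threshold, seed=config.seed,
                character_id=char, n_restarts=config.n_restarts,
                bounds=config.rate_bounds,
            )
            best = cls.fits[cls.best_model]
            rows.append({
                "character_id": char,
                "best_model": cls.best_model,
                "classified": cls.classified,
                "consensus_count": cls.consensus_count,
                "n_runs": cls.n_runs,
                **{f"aic_{m}": f.aic for m, f in cls.fits.items()},
                **{f"lnL_{m}": f.log_likelihood for m, f in cls.fits.items()},
                **{name: getattr(best.rates, name) for name in RATE_NAMES},
            })
            pci_per_run[char] = [
                pci_from_rates(r) for r in cls.mutual_rates_per_run
            ]
        cls_df = pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["character_id", "best_model", "classified",
                     "consensus_count", "n_runs", *RATE_NAMES]
        )
        _write_tsv(cls_df, out / "classifications.tsv")
        if rows:
            counts = cls_df.groupby("best_model").size().to_dict()
            logger.info("classification: %s", counts)
        if config.truth_path and rows:
            truth = pd.read_csv(config.truth_path, sep="\t", index_col=0)
            confusion: dict[tuple[str, str], int] = {}
            for row in rows:
                gene = row["character_id"]
                if gene in truth.index:
                    key = (str(truth.loc[gene, "model"]), row["best_model"])
                    confusion[key] = confusion.get(key, 0) + 1
            logger.info(
                "classification confusion (truth -> called): %s",
                {f"{t}->{c}": n for (t, c), n in sorted(confusion.items())},
            )

        # stage 3: client index
        if pci_per_run:
            top_k = min(config.top_k, len(pci_per_run))
            scores = rank_clients(
                pci_per_run, top_k=top_k,
                agree_threshold=config.agree_threshold,
            )
            pci_df = pd.DataFrame([
                {"character_id": s.character_id, "pci_mean": s.pci_mean,
                 "n_runs_in_top_set": s.n_runs_in_top_set,
                 "putative_client": s.putative_client}
                for s in scores
            ])
            _write_tsv(pci_df, out / "pci.tsv")
            logger.info("client index: %d putative clients of %d scored",
                        int(pci_df["putative_client"].sum()), len(pci_df))
        else:
            _write_tsv(
                pd.DataFrame(columns=["character_id", "pci_mean",
                                      "n_runs_in_top_set", "putative_client"]),
                out / "pci.tsv",
            )

        # stage 4: enrichment of the associated set
        if config.annotations_path:
            annotations = load_annotations(config.annotations_path)
            background = [c for c in matrix.characters
                          if c != config.focal_character]
            records = hypergeom_enrichment(
                associated, annotations, background, fdr=config.fdr
            )
            enr_df = pd.DataFrame(
                [dataclasses.asdict(r) for r in records]
            ) if records else pd.DataFrame(
                columns=["category", "k", "n", "K", "N", "p_value",
                         "q_value", "significant"]
            )
            _write_tsv(enr_df, out / "enrichment.tsv")
            logger.info("enrichment: %d significant categories",
                        int(enr_df["significant"].sum()) if len(enr_df) else 0)
        return out
    except CoevoscanError as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_trait_screen(config: RunConfig) -> Path:
    """Trait-mode pipeline: for each recoded trait, prune the tree to
    annotated taxa and test/classify its co-evolution with the focal gene.

    Writes ``traits.tsv`` with one row per analyzable trait: LRT consensus,
    best model, and the focal gene's gain/loss rates with the trait absent
    (q12, q21) versus present (q34, q43) under the best mutual fit. Traits
    with fewer than 3 annotated taxa are skipped with a warning.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    tree = dm.load_tree(Path(config.tree_path).read_text(), config.epsilon)
    matrix = dm.load_matrix(Path(config.matrix_path).read_text())
    vocab = (
        dm.load_trait_vocab(Path(config.trait_vocab_path).read_text())
        if config.trait_vocab_path
        else None
    )
    traits = dm.recode_traits(
        dm.load_traits(Path(config.traits_path).read_text()), vocab=vocab
    )
    rows = []
    for trait in traits.trait_names:
        try:
            trait_tree, states = dm.prune_to_trait(tree, traits, trait)
        except InsufficientDataError as exc:
            logger.warning("skipping trait %r: %s", trait, exc)
            continue
        state_series = pd.Series(states, index=trait_tree.taxon_labels)
        try:
            sub_tree, sub_matrix = dm.align_tree_and_matrix(trait_tree, matrix)
        except InsufficientDataError as exc:
            logger.warning("skipping trait %r: %s", trait, exc)
            continue
        if config.focal_character not in sub_matrix.characters:
            logger.warning("skipping trait %r: focal character missing", trait)
            continue
        tl = TreeLikelihood(sub_tree)
        h = sub_matrix.states.loc[tl.leaf_labels,
                                  config.focal_character].to_numpy(np.int64)
        trait_states = state_series.loc[tl.leaf_labels].to_numpy(np.int64)
        tips = joint_states(h, trait_states)
        if len(np.unique(h)) < 2 or len(np.unique(trait_states)) < 2:
            logger.warning("skipping trait %r: invariant character", trait)
            continue
        cls = classify_model(
            tl, tips, n_runs=config.n_runs,
            agree_threshold=config.agree_threshold, seed=config.seed,
            character_id=trait, n_restarts=config.n_restarts,
            bounds=config.rate_bounds,
        )
        mut = cls.fits["mutual"].rates
        from .screen import lrt_association

        assoc = lrt_association(cls.fits["independent"], cls.fits["mutual"])
        if np.allclose(h, trait_states) or np.allclose(h, 1 - trait_states):
            logger.warning(
                "trait %r is identical (or complementary) to the focal "
                "character; rates are degenerate", trait,
            )
        rows.append({
            "trait": trait,
            "n_taxa": len(trait_states),
            "lr_statistic": assoc.lr_statistic,
            "p_value": assoc.p_value,
            "best_model": cls.best_model,
            "classified": cls.classified,
            "consensus_count": cls.consensus_count,
            "focal_gain_trait_absent": mut.q12,
            "focal_gain_trait_present": mut.q34,
            "focal_loss_trait_absent": mut.q21,
            "focal_loss_trait_present": mut.q43,
        })
    _write_tsv(pd.DataFrame(rows), out / "traits.tsv")
    return out
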