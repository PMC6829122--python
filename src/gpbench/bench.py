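"""Benchmark orchestration and comparison statistics.

Runs the full protocol — replicated 80/20 hold-outs, per-replicate feature
selection and hyperparameter search confined to training lines, model
training, test-set prediction — and computes the comparison statistics:
Pearson r and MSE on held-out lines, mean r with "% of best r" / rank /
variance summaries, pairwise win-percentage matrices across replicates,
ensemble (mean) predictions over 5 or 11 member algorithms, and one-sided
paired Wilcoxon signed-rank tests with Benjamini-Hochberg q-values for
before/after comparisons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .datatypes import AlignmentError, GenotypeMatrix, PhenotypeTable, SplitPlan
from .kernels_trees import HyperGrid, default_hypergrid, fit_svr, fit_tree_ensemble
from .linear import fit_bayesian_regression, fit_ridge_blup, predict_linear
from .nets import (
    AnnArchitecture,
    CnnSettings,
    build_train_cnn,
    seed_hidden_weights,
    train_ann,
    xavier_init,
    mlp_layer_shapes,
)
from .select import rank_markers, select_top_k

__all__ = [
    "CellResult",
    "BenchmarkOutput",
    "EnsembleMembershipError",
    "EN_11_MEMBERS",
    "EN_5_MEMBERS",
    "grid_search",
    "evaluate_predictions",
    "ensemble_predict",
    "summarize_benchmark",
    "win_percentage_matrix",
    "paired_improvement_test",
    "percent_improvement",
    "run_benchmark",
    "derive_seed",
]

EN_11_MEMBERS = (
    "rrBLUP", "BRR", "BA", "BB", "BL",
    "SVR_lin", "SVR_poly", "SVR_rbf", "RF", "GTB", "ANN",
)
EN_5_MEMBERS = ("rrBLUP", "BL", "SVR_poly", "RF", "ANN")


class EnsembleMembershipError(KeyError):
    """A requested ensemble member has no predictions."""


class GridSearchError(RuntimeError):
    """Every candidate in the hyperparameter grid failed."""


def derive_seed(master_seed: int, *coords) -> int:
    """Deterministic per-cell seed from the master seed and coordinates.

    A stable hash of ``(master_seed, *coords)`` keeps every (algorithm,
    trait, replicate) cell independently re-runnable. Always < 2^31.
    """
    key = json.dumps([int(master_seed), *[str(c) for c in coords]])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class CellResult:
    """One (algorithm, trait, replicate) outcome on the held-out test lines."""

    algorithm: str
    trait: str
    replicate: int
    predictions: np.ndarray
    y_true: np.ndarray
    r: float
    mse: float
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    degenerate: bool = False
    training_checksum: str | None = None
    error: str | None = None


@dataclass
class BenchmarkOutput:
    """Everything `run_benchmark` produces."""

    results: list[CellResult]
    summary: pd.DataFrame
    win_matrices: dict[str, pd.DataFrame]

    def results_frame(self) -> pd.DataFrame:
        """Tidy per-replicate table (for external statistics, e.g. ANOVA)."""
        return pd.DataFrame(
            [
                {
                    "algorithm": c.algorithm,
                    "trait": c.trait,
                    "replicate": c.replicate,
                    "r": c.r,
                    "mse": c.mse,
                    "degenerate": c.degenerate,
                    "error": c.error,
                }
                for c in self.results
            ]
        )


def evaluate_predictions(y_pred, y_true) -> tuple[float, float]:
    """Pearson r and MSE between predicted and true test-line trait values.

    Constant predictions leave r undefined (NaN, a degenerate model); the
    MSE is still returned.
    """
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape or y_pred.ndim != 1:
        raise AlignmentError("prediction and truth vectors must match")
    if len(y_true) < 3:
        raise ValueError("need at least 3 test lines")
    mse = float(np.mean((y_pred - y_true) ** 2))
    if np.ptp(y_pred) == 0.0 or np.ptp(y_true) == 0.0:
        return float("nan"), mse
    r = float(np.corrcoef(y_pred, y_true)[0, 1])
    return r, mse


def ensemble_predict(
    predictions: dict[str, np.ndarray], membership="EN_11"
) -> np.ndarray:
    """Per-line arithmetic mean of member-algorithm predictions.

    ``membership`` is ``"EN_11"``, ``"EN_5"`` or an explicit sequence of
    member algorithm names; every member must have predictions for the same
    lines.
    """
    if membership == "EN_11":
        members: Sequence[str] = EN_11_MEMBERS
    elif membership == "EN_5":
        members = EN_5_MEMBERS
    else:
        members = tuple(membership)
    missing = [m for m in members if m not in predictions]
    if missing:
        raise EnsembleMembershipError(
            f"missing member predictions: {', '.join(missing)}"
        )
    mat = np.vstack([np.asarray(predictions[m], dtype=float) for m in members])
    if len({row.shape for row in mat}) > 1:
        raise AlignmentError("members predict different numbers of lines")
    return mat.mean(axis=0)


def summarize_benchmark(results: Sequence[CellResult]) -> pd.DataFrame:
    """Per (algorithm, trait): mean r, % of best r, rank, variance of r.

    Means are over replicates; degenerate replicates (undefined r) are
    excluded from the mean with a count.  "% of best" scales each
    algorithm's mean r by the best mean r within the trait (the best
    algorithm(s) sit at 100); ranks are tie-averaged.
    """
    rows = []
    for c in results:
        rows.append(
            {
                "algorithm": c.algorithm,
                "trait": c.trait,
                "replicate": c.replicate,
                "r": c.r,
                "mse": c.mse,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no results to summarize")

    def _agg(g: pd.DataFrame) -> pd.Series:
        valid = g["r"].dropna()
        return pd.Series(
            {
                "mean_r": valid.mean() if len(valid) else np.nan,
                "var_r": valid.var(ddof=1) if len(valid) > 1 else np.nan,
                "mean_mse": g["mse"].mean(),
                "n_replicates": len(g),
                "n_degenerate": int(g["r"].isna().sum()),
            }
        )

    summary = (
        df.groupby(["trait", "algorithm"]).apply(_agg, include_groups=False)
        .reset_index()
    )
    summary["pct_of_best"] = summary.groupby("trait")["mean_r"].transform(
        lambda s: 100.0 * s / s.max()
    )
    summary["rank"] = summary.groupby("trait")["mean_r"].rank(
        ascending=False, method="average"
    )
    return summary


def win_percentage_matrix(
    results: Sequence[CellResult], trait: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise strict-win percentages across replicates for one trait.

    Entry [a, b] is the percentage of shared replicates where a's test r
    strictly exceeds b's; ties are returned in a separate matrix so that
    ``wins[a,b] + wins[b,a] + ties[a,b] = 100`` for every pair.
    """
    cells = [c for c in results if trait is None or c.trait == trait]
    by_alg: dict[str, dict[int, float]] = {}
    for c in cells:
        by_alg.setdefault(c.algorithm, {})[c.replicate] = c.r
    algs = sorted(by_alg)
    rep_sets = {frozenset(v) for v in by_alg.values()}
    if len(rep_sets) > 1:
        raise AlignmentError("algorithms do not share the same replicate set")
    reps = sorted(next(iter(rep_sets))) if rep_sets else []
    wins = pd.DataFrame(0.0, index=algs, columns=algs)
    ties = pd.DataFrame(0.0, index=algs, columns=algs)
    for a in algs:
        for b in algs:
            if a == b:
                ties.loc[a, b] = 100.0
                continue
            wa = sum(by_alg[a][r] > by_alg[b][r] for r in reps)
            tie = sum(by_alg[a][r] == by_alg[b][r] for r in reps)
            wins.loc[a, b] = 100.0 * wa / len(reps)
            ties.loc[a, b] = 100.0 * tie / len(reps)
    return wins, ties


def paired_improvement_test(
    r_before: Sequence[float],
    r_after: Sequence[float],
    alternative: str = "greater",
) -> tuple[float, bool]:
    """One-sided paired Wilcoxon signed-rank test that r increased.

    Returns ``(p_value, all_zero_flag)``; when every paired difference is
    zero there is no evidence of change and p = 1 is returned with the flag
    set.  The exact null distribution is used when feasible (small n, no
    ties), following scipy's convention.
    """
    before = np.asarray(r_before, dtype=float)
    after = np.asarray(r_after, dtype=float)
    if before.shape != after.shape:
        raise AlignmentError("paired vectors must have equal length")
    diffs = after - before
    if np.all(diffs == 0):
        return 1.0, True
    res = stats.wilcoxon(after, before, alternative=alternative)
    return float(res.pvalue), False


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for a family of tests."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def percent_improvement(
    r_baseline: float, r_new: float, round_to_percent: bool = True
) -> float:
    """Relative change in r, in percent: 100 (r_new - r_base) / r_base."""
    if r_baseline == 0:
        raise ZeroDivisionError("baseline r is zero; percent change undefined")
    pct = 100.0 * (r_new - r_baseline) / r_baseline
    return float(round(pct)) if round_to_percent else float(pct)


# ---------------------------------------------------------------------------
# model registry: one uniform fit/predict adapter per algorithm


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:16]


def _fit_predict(
    algorithm: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None,
    y_val: np.ndarray | None,
    X_test: np.ndarray,
    hp: dict[str, Any],
    seed: int,
    sampler_iterations: int = 12_000,
    sampler_burn_in: int = 2_000,
    ann_max_epochs: int = 500,
) -> tuple[np.ndarray, str]:
    """Train one algorithm and predict the test lines.

    Returns (test predictions, checksum of the learned training artifact).
    The checksum covers marker effects / importances / network weights and
    is used by the leakage audit: it must not change when test-set
    phenotypes change.
    """
    if algorithm == "rrBLUP":
        fit = fit_ridge_blup(X_train, y_train)
        return predict_linear(fit, X_test), _checksum(fit.marker_effects)
    if algorithm in ("BRR", "BA", "BB", "BL"):
        from .linear import BayesPrior

        prior = BayesPrior(**{k: v for k, v in hp.items() if k in ("df", "pi_zero")})
        fit = fit_bayesian_regression(
            X_train,
            y_train,
            model=algorithm,
            iterations=sampler_iterations,
            burn_in=sampler_burn_in,
            prior=prior,
            seed=seed,
        )
        return predict_linear(fit, X_test), _checksum(fit.marker_effects)
    if algorithm in ("SVR_lin", "SVR_poly", "SVR_rbf"):
        kernel = algorithm.split("_")[1]
        fit = fit_svr(X_train, y_train, kernel=kernel, **hp)
        return fit.predict(X_test), _checksum(fit.estimator.dual_coef_)
    if algorithm in ("RF", "GTB"):
        fit = fit_tree_ensemble(X_train, y_train, family=algorithm, seed=seed, **hp)
        return fit.predict(X_test), _checksum(fit.importances)
    if algorithm.startswith("ANN"):
        arch = AnnArchitecture(**{k: v for k, v in hp.items() if k != "donor"})
        donor = hp.get("donor")
        if X_val is None or y_val is None:
            raise ValueError("ANN training requires a validation set")
        shapes = mlp_layer_shapes(X_train.shape[1], arch)
        base = xavier_init(shapes, seed)
        init = base
        reinit = None
        if donor is not None:
            donor_scores, center = _donor_scores(
                donor, X_train, y_train, seed,
                sampler_iterations, sampler_burn_in,
            )

            def reinit(attempt: int, _s=donor_scores, _c=center):
                fresh = xavier_init(shapes, derive_seed(seed, "restart", attempt))
                return seed_hidden_weights(
                    fresh, _s, noise_seed=derive_seed(seed, "noise", attempt),
                    center_scores=_c, donor_name=donor,
                )

            init = seed_hidden_weights(
                base, donor_scores, noise_seed=derive_seed(seed, "noise", -1),
                center_scores=center, donor_name=donor,
            )
        model, _ = train_ann(
            X_train, y_train, X_val, y_val, arch,
            init=init, max_epochs=ann_max_epochs, seed=seed, reinit=reinit,
        )
        return model.predict(X_test), _checksum(*model.weights)
    if algorithm == "CNN":
        if X_val is None or y_val is None:
            raise ValueError("CNN training requires a validation set")
        settings = CnnSettings(**hp)
        model, _ = build_train_cnn(
            _oh(X_train), y_train, _oh(X_val), y_val, settings, seed=seed
        )
        return model.predict(_oh(X_test)), _checksum(model.Wc, model.Wd)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _oh(X: np.ndarray) -> np.ndarray:
    from .nets import one_hot_encode

    return one_hot_encode(np.asarray(X).astype(np.int8))


def _donor_scores(
    donor: str, X_train, y_train, seed, iterations, burn_in
) -> tuple[np.ndarray, bool]:
    """Marker scores from the seeding donor algorithm (training data only)."""
    if donor == "rrBLUP":
        return fit_ridge_blup(X_train, y_train).marker_effects, False
    if donor in ("BB", "BL", "BRR", "BA"):
        fit = fit_bayesian_regression(
            X_train, y_train, model=donor,
            iterations=iterations, burn_in=burn_in, seed=seed,
        )
        return fit.marker_effects, False
    if donor == "RF":
        fit = fit_tree_ensemble(X_train, y_train, family="RF", seed=seed)
        # non-negative importances: mean-center so seeds carry sign variation
        return fit.importances, True
    raise ValueError(f"unknown seeding donor {donor!r}")


def grid_search(
    algorithm: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: HyperGrid | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int | None = None,
    sampler_iterations: int = 1500,
    sampler_burn_in: int = 500,
    ann_max_epochs: int = 200,
) -> dict[str, Any]:
    """Pick the hyperparameter combination with lowest cross-validated MSE.

    Confined to training lines.  k-fold cross-validation (``folds`` folds,
    ``repeats`` repeats with different fold seeds) scores every combination
    for the scikit-learn-style algorithms; the neural networks instead use
    repeated inner 80/20 train/select splits of the training lines.  A
    single-candidate (or empty) grid is returned without any CV.  Selection
    uses MSE, not r.
    """
    grid = grid if grid is not None else default_hypergrid(algorithm)
    combos = grid.combinations()
    if len(combos) <= 1:
        return combos[0] if combos else {}

    n = X_train.shape[0]
    use_inner_holdout = algorithm.startswith("ANN") or algorithm == "CNN"
    rng = np.random.default_rng(seed)
    scores = np.zeros(len(combos))
    counts = np.zeros(len(combos))
    failures: list[str] = []

    for rep in range(repeats):
        if use_inner_holdout:
            perm = rng.permutation(n)
            n_sel = max(1, int(0.2 * n))
            sel, tr = perm[:n_sel], perm[n_sel:]
            splits = [(tr, sel)]
        else:
            kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
            splits = list(kf.split(np.arange(n)))
        for ci, hp in enumerate(combos):
            for tr, te in splits:
                try:
                    if use_inner_holdout:
                        n_val = max(1, int(0.2 * len(tr)))
                        val, core = tr[:n_val], tr[n_val:]
                        pred, _ = _fit_predict(
                            algorithm, X_train[core], y_train[core],
                            X_train[val], y_train[val], X_train[te], hp,
                            seed=derive_seed(seed or 0, "gs", rep, ci),
                            sampler_iterations=sampler_iterations,
                            sampler_burn_in=sampler_burn_in,
                            ann_max_epochs=ann_max_epochs,
                        )
                    else:
                        pred, _ = _fit_predict(
                            algorithm, X_train[tr], y_train[tr], None, None,
                            X_train[te], hp,
                            seed=derive_seed(seed or 0, "gs", rep, ci),
                            sampler_iterations=sampler_iterations,
                            sampler_burn_in=sampler_burn_in,
                        )
                    scores[ci] += float(np.mean((pred - y_train[te]) ** 2))
                    counts[ci] += 1
                except Exception as exc:  # candidate failed on this fold
                    failures.append(f"{hp}: {exc}")
                    scores[ci] += np.inf
                    counts[ci] += 1
    mean_scores = np.where(counts > 0, scores / np.maximum(counts, 1), np.inf)
    if not np.isfinite(mean_scores).any():
        raise GridSearchError(
            "all hyperparameter candidates failed: " + "; ".join(failures[:5])
        )
    return combos[int(np.argmin(mean_scores))]


def run_benchmark(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    algorithms: Sequence[str],
    split_plan: SplitPlan,
    master_seed: int = 0,
    grids: dict[str, HyperGrid] | None = None,
    do_grid_search: bool = False,
    feature_selection: dict | None = None,
    ensembles: Sequence[str] = (),
    sampler_iterations: int = 12_000,
    sampler_burn_in: int = 2_000,
    ann_max_epochs: int = 500,
    fixed_hyperparameters: dict[str, dict] | None = None,
) -> BenchmarkOutput:
    """End-to-end benchmark over algorithms x traits x replicates.

    For each replicate: split lines; optionally rank markers on the training
    lines and keep the top k (``feature_selection={"method": "RF", "k": 500,
    "exempt": ("RF",)}``; exempt algorithms see all markers); optionally run
    the hyperparameter search on training lines; train; predict the test
    lines.  Stage failures are recorded per cell and the run continues.
    Ensemble rows (``"EN_11"`` / ``"EN_5"``) average member predictions per
    replicate.  Every stochastic step gets a seed derived from
    ``master_seed`` and the cell coordinates, so any cell can be re-run in
    isolation.
    """
    grids = grids or {}
    fixed_hyperparameters = fixed_hyperparameters or {}
    results: list[CellResult] = []
    X_all = genotypes.X()

    for trait in phenotypes.trait_names:
        y_all = phenotypes.trait(trait)
        per_rep_predictions: list[dict[str, np.ndarray]] = []
        for rep, split in enumerate(split_plan.replicates):
            tr, va, te = split.train, split.validation, split.test
            X_tr_full, y_tr = X_all[tr], y_all[tr]
            X_va_full = X_all[va] if len(va) else None
            y_va = y_all[va] if len(va) else None
            X_te_full, y_te = X_all[te], y_all[te]

            sel_idx = None
            if feature_selection:
                fs_seed = derive_seed(master_seed, "fs", trait, rep)
                ranking = rank_markers(
                    X_tr_full, y_tr,
                    method=feature_selection.get("method", "RF"),
                    seed=fs_seed,
                )
                k = min(feature_selection.get("k", 8000), X_all.shape[1])
                sel_idx, _ = select_top_k(ranking, k)

            rep_preds: dict[str, np.ndarray] = {}
            for algorithm in algorithms:
                cell_seed = derive_seed(master_seed, algorithm, trait, rep)
                exempt = feature_selection.get("exempt", ()) if feature_selection else ()
                if sel_idx is not None and algorithm not in exempt:
                    X_tr = X_tr_full[:, sel_idx]
                    X_va = None if X_va_full is None else X_va_full[:, sel_idx]
                    X_te = X_te_full[:, sel_idx]
                else:
                    X_tr, X_va, X_te = X_tr_full, X_va_full, X_te_full
                try:
                    hp = dict(fixed_hyperparameters.get(algorithm, {}))
                    if do_grid_search:
                        searched = grid_search(
                            algorithm, X_tr, y_tr,
                            grid=grids.get(algorithm),
                            seed=derive_seed(master_seed, "gs", algorithm, trait, rep),
                        )
                        hp = {**searched, **hp}
                    pred, checksum = _fit_predict(
                        algorithm, X_tr, y_tr, X_va, y_va, X_te, hp,
                        seed=cell_seed,
                        sampler_iterations=sampler_iterations,
                        sampler_burn_in=sampler_burn_in,
                        ann_max_epochs=ann_max_epochs,
                    )
                    r, mse = evaluate_predictions(pred, y_te)
                    rep_preds[algorithm] = pred
                    results.append(
                        CellResult(
                            algorithm=algorithm, trait=trait, replicate=rep,
                            predictions=pred, y_true=y_te, r=r, mse=mse,
                            hyperparameters=hp, seed=cell_seed,
                            degenerate=bool(np.isnan(r)),
                            training_checksum=checksum,
                        )
                    )
                except Exception as exc:
                    results.append(
                        CellResult(
                            algorithm=algorithm, trait=trait, replicate=rep,
                            predictions=np.full(len(te), np.nan),
                            y_true=y_te, r=float("nan"), mse=float("nan"),
                            seed=cell_seed, degenerate=True, error=str(exc),
                        )
                    )
            per_rep_predictions.append(rep_preds)

            for ens in ensembles:
                if ens == "EN_11":
                    members, name = EN_11_MEMBERS, "EN_11"
                elif ens == "EN_5":
                    members, name = EN_5_MEMBERS, "EN_5"
                else:
                    members = tuple(ens)
                    name = "EN(" + "+".join(members) + ")"
                usable = [m for m in members if m in rep_preds]
                if not usable:
                    continue
                pred = ensemble_predict(
                    {m: rep_preds[m] for m in usable}, membership=usable
                )
                r, mse = evaluate_predictions(pred, y_te)
                results.append(
                    CellResult(
                        algorithm=name, trait=trait, replicate=rep,
                        predictions=pred, y_true=y_te, r=r, mse=mse,
                        degenerate=bool(np.isnan(r)),
                        hyperparameters={"members": usable},
                    )
                )

    summary = summarize_benchmark(results)
    win_matrices = {}
    for trait in phenotypes.trait_names:
        wins, _ = win_percentage_matrix(results, trait=trait)
        win_matrices[trait] = wins
    return BenchmarkOutput(results=results, summary=summary, win_matrices=win_matrices)
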