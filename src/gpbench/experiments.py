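"""Canonical desk-scale experiments.

Each function runs one self-contained study on synthetic data and returns a
plain dict of the numbers it measured.  They are shared by the analysis
drivers, the test suite and the reproduction script, so every reported
number is recomputed from scratch by the same code path.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .bench import derive_seed, evaluate_predictions
from .linear import fit_bayesian_regression, fit_ridge_blup
from .nets import AnnArchitecture, train_ann
from .select import overlap_null_percentile, rank_markers, select_top_k
from .simulate import make_split_plan, simulate_genotypes, simulate_trait

__all__ = [
    "overlap_null_experiment",
    "parameter_recovery_experiment",
    "ann_feature_selection_experiment",
]


def overlap_null_experiment(
    seed: int,
    p_total: int = 332_178,
    k: int = 8_000,
    n_sets: int = 3,
    n_permutations: int = 10_000,
) -> dict:
    """Random-overlap null for three independently selected top-k marker sets.

    Draws three uniform subsets of ``k`` of the ``p_total`` markers, records
    the size of their common intersection, repeats ``n_permutations`` times,
    and reports the 99th percentile alongside the permutation mean and the
    analytic expectation ``p (k/p)^3``.  The defaults match a genome-scale
    marker panel (332,178 markers, top 8,000 selected).
    """
    res = overlap_null_percentile(
        p_total, k, n_sets=n_sets, n_permutations=n_permutations,
        percentile=99.0, seed=seed,
    )
    return {
        "percentile_99": res.percentiles[99.0],
        "mean_overlap": res.mean,
        "analytic_mean": res.analytic_mean(),
        "se_mean": float(res.overlap_counts.std(ddof=1) / np.sqrt(n_permutations)),
        "n_permutations": n_permutations,
    }


def parameter_recovery_experiment(
    seed: int,
    n_lines: int = 1000,
    n_markers: int = 200,
    n_qtl: int = 20,
    h2: float = 0.7,
    n_seeds: int = 10,
    iterations: int = 4000,
    burn_in: int = 1000,
) -> dict:
    """Marker-effect recovery on an additive trait.

    Simulates ``n_seeds`` independent datasets, fits ridge-BLUP and BayesA
    on each, and reports the median correlation between estimated and true
    per-marker effects.
    """
    corr_ridge, corr_ba = [], []
    for i in range(n_seeds):
        s = derive_seed(seed, "recovery", i)
        G = simulate_genotypes(n_lines, n_markers, seed=s)
        pheno, truth = simulate_trait(
            G, n_qtl=n_qtl, h2=h2, architecture="additive", seed=s + 1
        )
        y = pheno.values[:, 0]
        beta_true = truth.full_effect_vector(n_markers)
        fit_r = fit_ridge_blup(G, y)
        corr_ridge.append(float(np.corrcoef(fit_r.marker_effects, beta_true)[0, 1]))
        fit_b = fit_bayesian_regression(
            G, y, model="BA", iterations=iterations, burn_in=burn_in, seed=s + 2
        )
        corr_ba.append(float(np.corrcoef(fit_b.marker_effects, beta_true)[0, 1]))
    return {
        "median_corr_ridge": float(np.median(corr_ridge)),
        "median_corr_ba": float(np.median(corr_ba)),
        "corr_ridge": corr_ridge,
        "corr_ba": corr_ba,
        "n_seeds": n_seeds,
    }


def ann_feature_selection_experiment(
    seed: int,
    n_lines: int = 400,
    n_markers: int = 8000,
    n_qtl: int = 20,
    h2: float = 0.6,
    k_select: int = 500,
    n_seeds: int = 10,
    max_epochs: int = 600,
) -> dict:
    """Does training-only feature selection help the neural network when
    markers vastly outnumber lines (p:n = 20)?

    Per seed: simulate a moderately oligogenic additive trait (20 QTL, so
    that a top-500 marker panel can actually carry the signal at this sample
    size), hold out 20% of lines, carve a validation slice from the training
    lines, rank markers by Random Forest importance on the training lines
    only, and train the same multilayer perceptron twice — on all markers
    and on the top ``k_select``.  The network uses the sigmoid activation
    (with 8,000 inputs the ReLU variant routinely collapses to constant
    output, the degeneracy the restart rule guards against).  A network
    still degenerate after all restarts is scored r = 0 (no predictive
    ability).  Reports per-seed test-set r for both arms, their medians, and
    a one-sided sign test that selection improves r.
    """
    from .nets import TrainingFailedError

    arch = AnnArchitecture(
        hidden_layer_sizes=(50,), activation="sigmoid",
        dropout_rate=0.10, l2_penalty=0.0, learning_rate=1e-3,
    )
    r_all, r_sel = [], []
    n_failed = 0
    for i in range(n_seeds):
        s = derive_seed(seed, "annfs", i)
        G = simulate_genotypes(n_lines, n_markers, seed=s)
        pheno, _ = simulate_trait(
            G, n_qtl=n_qtl, h2=h2, architecture="additive", seed=s + 1
        )
        y = pheno.values[:, 0]
        plan = make_split_plan(
            n_lines, test_fraction=0.2, n_replicates=1,
            validation_fraction_of_train=0.2, seed=s + 2,
        )
        sp = plan.replicates[0]
        X = G.X()
        Xtr, ytr = X[sp.train], y[sp.train]
        Xva, yva = X[sp.validation], y[sp.validation]
        Xte, yte = X[sp.test], y[sp.test]

        try:
            model_all, _ = train_ann(
                Xtr, ytr, Xva, yva, arch, max_epochs=max_epochs, seed=s + 3
            )
            r_a, _ = evaluate_predictions(model_all.predict(Xte), yte)
        except TrainingFailedError:
            r_a, n_failed = 0.0, n_failed + 1

        ranking = rank_markers(Xtr, ytr, method="RF", seed=s + 4)
        idx, _ = select_top_k(ranking, k_select)
        try:
            model_sel, _ = train_ann(
                Xtr[:, idx], ytr, Xva[:, idx], yva, arch,
                max_epochs=max_epochs, seed=s + 3,
            )
            r_s, _ = evaluate_predictions(model_sel.predict(Xte[:, idx]), yte)
        except TrainingFailedError:
            r_s, n_failed = 0.0, n_failed + 1
        r_all.append(r_a)
        r_sel.append(r_s)

    wins = int(np.sum(np.asarray(r_sel) > np.asarray(r_all)))
    sign_p = float(stats.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue)
    return {
        "r_without_selection": r_all,
        "r_with_selection": r_sel,
        "median_r_without": float(np.median(r_all)),
        "median_r_with": float(np.median(r_sel)),
        "selection_wins": wins,
        "sign_test_p": sign_p,
        "n_seeds": n_seeds,
        "n_training_failures": n_failed,
    }
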