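"""Synthetic genotype/phenotype simulator.

Generates the data regimes a genomic-prediction benchmark has to cope with:
biallelic markers coded {-1, 0, 1}, marker:line (p:n) ratios from ~1 up to
several hundred, additive and epistatic trait architectures, and a target
heritability.  Phenotypes are min-max normalized to [0, 1], matching the
convention used throughout the pipeline.

Markers are independent by default (no linkage disequilibrium); an optional
block-correlated mode duplicates markers with flip noise.  The simulator
records its ground truth (QTL positions, effects, genetic values, drawn
allele frequencies) so estimator contracts can be tested by parameter
recovery rather than by eyeballing.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    DegenerateTraitError,
    GenotypeMatrix,
    PhenotypeTable,
    ReplicateSplit,
    SplitPlan,
    TraitTruth,
)

__all__ = [
    "simulate_genotypes",
    "simulate_trait",
    "make_split_plan",
    "EFFECT_DISTRIBUTIONS",
]


def _draw_effects(rng: np.random.Generator, n: int, distribution: str) -> np.ndarray:
    if distribution == "normal":
        return rng.normal(0.0, 1.0, n)
    if distribution == "laplace":
        return rng.laplace(0.0, 1.0, n)
    if distribution == "sparse":
        # point-mass mixture: 20% large effects, 80% small
        big = rng.random(n) < 0.2
        eff = rng.normal(0.0, 0.25, n)
        eff[big] = rng.normal(0.0, 2.0, big.sum())
        return eff
    raise ValueError(f"unknown effect distribution {distribution!r}")


EFFECT_DISTRIBUTIONS = ("normal", "laplace", "sparse")

ARCHITECTURES = ("additive", "additive_plus_epistatic", "epistatic_only")


def simulate_genotypes(
    n_lines: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    inbred: bool = False,
    seed: int | None = None,
    ld_blocks: int = 1,
    ld_flip_prob: float = 0.05,
) -> GenotypeMatrix:
    """Draw a lines x markers genotype matrix.

    Each marker gets its own ``A``-allele frequency drawn uniformly from
    ``maf_range``.  Outbred mode samples genotypes from Hardy-Weinberg
    proportions (aa/Aa/AA with probabilities (1-f)^2, 2f(1-f), f^2); inbred
    mode emits only homozygotes {-1, 1} with P(AA) = f.

    ``ld_blocks > 1`` produces crude linkage blocks: markers within a block
    are copies of a template column with entries re-drawn independently with
    probability ``ld_flip_prob``.

    Returns a :class:`GenotypeMatrix` whose ``allele_freqs`` records the
    drawn frequencies.
    """
    if n_lines < 2 or n_markers < 1:
        raise ValueError("need n_lines >= 2 and n_markers >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if ld_blocks < 1:
        raise ValueError("ld_blocks must be >= 1")
    rng = np.random.default_rng(seed)

    freqs = rng.uniform(lo, hi, n_markers)

    def _draw_column(f: float, size: int) -> np.ndarray:
        if inbred:
            return np.where(rng.random(size) < f, 1, -1).astype(np.int8)
        return (rng.binomial(2, f, size) - 1).astype(np.int8)

    if ld_blocks == 1:
        if inbred:
            calls = np.where(rng.random((n_lines, n_markers)) < freqs, 1, -1)
        else:
            calls = rng.binomial(2, freqs, (n_lines, n_markers)) - 1
        calls = calls.astype(np.int8)
    else:
        calls = np.empty((n_lines, n_markers), dtype=np.int8)
        block_of = np.array_split(np.arange(n_markers), ld_blocks)
        for block in block_of:
            if len(block) == 0:
                continue
            f = freqs[block[0]]
            freqs[block] = f
            template = _draw_column(f, n_lines)
            for j in block:
                col = template.copy()
                flip = rng.random(n_lines) < ld_flip_prob
                col[flip] = _draw_column(f, int(flip.sum()))
                calls[:, j] = col

    return GenotypeMatrix(
        line_ids=[f"line{i}" for i in range(n_lines)],
        marker_ids=[f"m{j}" for j in range(n_markers)],
        calls=calls,
        allele_freqs=freqs,
    )


def simulate_trait(
    genotypes: GenotypeMatrix,
    n_qtl: int,
    h2: float,
    architecture: str = "additive",
    effect_distribution: str = "normal",
    seed: int | None = None,
    trait_name: str = "trait",
    n_epistatic_pairs: int | None = None,
    center_epistasis: bool = True,
    normalize: bool = True,
) -> tuple[PhenotypeTable, TraitTruth]:
    """Simulate one trait on top of an existing genotype matrix.

    The genetic value of line i is

        g_i = sum_q a_q x_iq  +  sum_(j,k) e_jk x_ij x_ik

    over ``n_qtl`` causal markers; for epistatic architectures, QTL are paired
    at random and a multiplicative interaction effect added (marker columns
    are mean-centered before forming products when ``center_epistasis`` so the
    interaction is orthogonal to the main effects at allele frequency 0.5).
    Environmental noise is Gaussian with variance chosen so that
    var(g)/var(y) equals ``h2`` in expectation; the phenotype is then min-max
    normalized to [0, 1].

    Returns the phenotype table and a :class:`TraitTruth` recording QTL,
    effects and pre-noise genetic values.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0, 1]")
    if n_qtl > genotypes.n_markers:
        raise ValueError("n_qtl cannot exceed the number of markers")
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")

    rng = np.random.default_rng(seed)
    n, p = genotypes.calls.shape
    X = genotypes.X()

    qtl = np.sort(rng.choice(p, size=n_qtl, replace=False))

    additive = np.zeros(n_qtl)
    if architecture in ("additive", "additive_plus_epistatic"):
        additive = _draw_effects(rng, n_qtl, effect_distribution)

    pairs: list[tuple[int, int, float]] = []
    g = X[:, qtl] @ additive
    if architecture in ("additive_plus_epistatic", "epistatic_only"):
        if n_epistatic_pairs is None:
            n_epistatic_pairs = max(1, n_qtl // 2)
        perm = rng.permutation(n_qtl)
        Xq = X[:, qtl]
        if center_epistasis:
            Xq = Xq - Xq.mean(axis=0)
        eff = _draw_effects(rng, n_epistatic_pairs, effect_distribution)
        for k in range(n_epistatic_pairs):
            a = int(perm[(2 * k) % n_qtl])
            b = int(perm[(2 * k + 1) % n_qtl])
            if a == b:
                continue
            term = Xq[:, a] * Xq[:, b]
            if center_epistasis:
                term = term - term.mean()
            g = g + eff[k] * term
            pairs.append((int(qtl[a]), int(qtl[b]), float(eff[k])))

    var_g = float(np.var(g))
    if h2 == 1.0:
        if var_g == 0.0:
            raise DegenerateTraitError(
                "genetic values are constant; cannot build a noiseless trait"
            )
        y = g.copy()
    elif h2 == 0.0:
        y = rng.normal(0.0, 1.0, n)
    else:
        if var_g == 0.0:
            raise DegenerateTraitError("genetic values are constant")
        sd_e = np.sqrt(var_g * (1.0 - h2) / h2)
        y = g + rng.normal(0.0, sd_e, n)

    if normalize:
        rng_y = y.max() - y.min()
        if rng_y == 0.0:
            raise DegenerateTraitError("phenotype is constant")
        y = (y - y.min()) / rng_y

    phenotypes = PhenotypeTable(
        line_ids=list(genotypes.line_ids),
        trait_names=[trait_name],
        values=y[:, None],
    )
    truth = TraitTruth(
        qtl_indices=qtl,
        additive_effects=additive,
        epistatic_pairs=pairs,
        heritability_target=h2,
        genetic_values=g,
    )
    return phenotypes, truth


def make_split_plan(
    n_lines: int,
    test_fraction: float = 0.2,
    n_replicates: int = 10,
    validation_fraction_of_train: float = 0.0,
    seed: int | None = None,
    mode: str = "independent",
) -> SplitPlan:
    """Build the replicated hold-out design.

    Per replicate, ``floor(test_fraction * n)`` lines (at least 1) are held
    out as the test set and the remainder train; a validation slice may be
    carved from the training lines only.  ``mode="independent"`` samples each
    replicate's test set independently (a different random 20% each time);
    ``mode="partition"`` instead cycles through a disjoint partition of the
    lines.  Bit-reproducible from ``(n_lines, fractions, seed)``.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    if not (0.0 <= validation_fraction_of_train < 1.0):
        raise ValueError("validation_fraction_of_train must be in [0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n_test = max(1, int(np.floor(test_fraction * n_lines)))
    if n_lines - n_test < 1:
        raise ValueError("n_lines too small for the requested test fraction")

    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_replicates)

    replicates: list[ReplicateSplit] = []
    if mode == "partition":
        part_rng = np.random.default_rng(master.spawn(1)[0])
        order = part_rng.permutation(n_lines)
    elif mode != "independent":
        raise ValueError("mode must be 'independent' or 'partition'")

    for r in range(n_replicates):
        rng = np.random.default_rng(child_seeds[r])
        if mode == "independent":
            perm = rng.permutation(n_lines)
            test = np.sort(perm[:n_test])
        else:
            start = (r * n_test) % n_lines
            idx = (np.arange(n_test) + start) % n_lines
            test = np.sort(order[idx])
        train = np.setdiff1d(np.arange(n_lines), test)
        val = np.empty(0, dtype=int)
        if validation_fraction_of_train > 0:
            n_val = max(1, int(np.floor(validation_fraction_of_train * len(train))))
            vperm = rng.permutation(len(train))
            val = np.sort(train[vperm[:n_val]])
            train = np.setdiff1d(train, val)
        replicates.append(ReplicateSplit(train=train, test=test, validation=val))

    return SplitPlan(
        n_lines=n_lines,
        test_fraction=test_fraction,
        validation_fraction_of_train=validation_fraction_of_train,
        master_seed=-1 if seed is None else int(seed),
        replicates=replicates,
    )
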