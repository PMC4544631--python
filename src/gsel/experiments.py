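"""Canned study workflows: calibration checks and simulation experiments.

These functions bundle the package's main end-to-end computations at fixed,
documented problem sizes so they can be re-run reproducibly (each takes a
single seed).  They back the reproduction script and the statistical test
suite.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CVScheme, accuracy, qtl_sharing_experiment, run_cv, split_single
from .io import intersect_markers
from .predictors import (
    BayesianLassoGEBV,
    BayesianRidgeGEBV,
    GibbsConfig,
    RidgeBLUP,
    center_markers,
    gblup,
)
from .simulate import (
    TraitArchitecture,
    as_rng,
    draw_architecture,
    mean_junction_count,
    random_cross_plan,
    simulate_founders,
    simulate_population,
    simulate_trait,
    study_populations,
    uniform_map,
)


def _polymorphic_panel(m):
    """Restrict a population to its segregating markers (its marker panel)."""
    keep = [mid for mid, k in zip(m.marker_ids, m.polymorphic_mask()) if k]
    return m.subset_markers(keep)


def ridge_oracle_equivalence(seed: int = 0, n: int = 100, p: int = 300,
                             burn_in: int = 20_000, n_iter: int = 120_000) -> dict:
    """Bayesian ridge posterior means against the closed-form ridge solution.

    Simulates a polygenic trait (every marker carries a small normal effect,
    h2 about 0.6) on an n x p Bernoulli(0.5) design and fits the Gibbs
    sampler with moderately informative variance priors (df 30 at the
    simulation scale), so the variance posterior concentrates and the
    plug-in ridge with ``lambda = E[s2_e]/E[s2_beta]`` is the matching
    closed form.  Returns the effect-vector correlation and the maximum
    absolute difference relative to the effect spread.
    """
    rng = as_rng(seed)
    X = rng.integers(0, 2, size=(n, p)).astype(float)
    beta = rng.normal(0.0, 0.15, size=p)
    g = X @ beta
    y = g + rng.normal(0.0, np.std(g) * np.sqrt(2.0 / 3.0), size=n)
    cfg = GibbsConfig(
        S_eps=1.0, df_eps=30.0, S_beta=0.02, df_beta=30.0,
        burn_in=burn_in, n_iter=n_iter, seed=int(rng.integers(2**31)),
    )
    brr = BayesianRidgeGEBV(config=cfg).fit(X, y)
    lam = brr.diagnostics_["sigma2_e_mean"] / brr.diagnostics_["sigma2_beta_mean"]
    ridge = RidgeBLUP(lam=lam).fit(X, y)
    diff = brr.marker_effects_ - ridge.marker_effects_
    return {
        "correlation": float(np.corrcoef(brr.marker_effects_, ridge.marker_effects_)[0, 1]),
        "max_abs_diff_over_sd": float(np.max(np.abs(diff)) / np.std(ridge.marker_effects_)),
        "matched_lambda": float(lam),
        "n": n,
    }


def dual_identity(seed: int = 0, n: int = 20, p: int = 50) -> dict:
    """RR-BLUP/GBLUP duality: predictions from the kinship form K = Xc Xc'/c
    must equal ridge predictions with lambda = c * delta."""
    rng = as_rng(seed)
    X = rng.integers(0, 2, size=(n, p)).astype(float)
    y = rng.normal(0.0, 1.0, size=n)
    Xc, _ = center_markers(X)
    c, delta = 7.3, 2.1
    K = Xc @ Xc.T / c
    pred_k, _ = gblup(K, y, delta=delta)
    pred_r = RidgeBLUP(lam=c * delta).fit(X, y).predict(X)
    return {"max_abs_diff": float(np.max(np.abs(pred_k - pred_r))), "n": n}


def heritability_calibration(seed: int = 0, h2_levels=(0.3, 0.6), n_reps: int = 200,
                             markers_per_chromosome: int = 40) -> dict:
    """Mean realized heritability Var(g)/Var(y) of the trait simulator over
    repeated architecture and noise draws in one ~350-line population."""
    rng = as_rng(seed)
    pop, _, _ = study_populations(seed=rng, markers_per_chromosome=markers_per_chromosome)
    poly = np.flatnonzero(pop.polymorphic_mask())
    out = {}
    for h2 in h2_levels:
        realized = []
        for _ in range(n_reps):
            arch = draw_architecture(poly, 100, 1.0, rng, h2=h2)
            y, g = simulate_trait(pop, arch, rng)
            realized.append(np.var(g, ddof=1) / np.var(y, ddof=1))
        out[h2] = float(np.mean(realized))
    out["n"] = pop.n_lines
    return out


def map_expansion(seed: int = 0, lines_per_type: int = 1000,
                  markers_per_chromosome: int = 40) -> dict:
    """Mean recombination-junction count of RIL(F8) versus DH lines on a
    21 x 150 cM genome; single-seed-descent RILs approach twice the DH
    junction density."""
    rng = as_rng(seed)
    gmap = uniform_map(21, 150.0, markers_per_chromosome)
    founders = simulate_founders(40, gmap, seed=rng)
    n_crosses = lines_per_type // 10
    res = {}
    for ltype in ("DH", "RIL"):
        plan = random_cross_plan(
            founders.parent_ids, n_crosses, 10, line_type=ltype,
            selfing_generations=8, seed=rng,
        )
        _, anc = simulate_population(founders, plan, seed=rng, return_ancestry=True)
        res[ltype] = mean_junction_count(anc, gmap, founders.marker_ids)
    res["ratio"] = res["RIL"] / res["DH"]
    res["n"] = 2 * n_crosses * 10
    return res


def split_sizes(n: int = 341, train_fraction: float = 0.8, seed: int = 0) -> dict:
    """Training/validation sizes of the 80/20 split at the given n."""
    tr, va = split_single(range(n), train_fraction, as_rng(seed))
    return {"n_train": len(tr), "n_valid": len(va), "n": n}


def single_population_cv(seed: int = 0, method: str = "RIDGE", h2: float = 0.82,
                         n_iterations: int = 200,
                         markers_per_chromosome: int = 40):
    """Standard within-population cross-validation on a simulated trait."""
    rng = as_rng(seed)
    pop, _, _ = study_populations(seed=rng, markers_per_chromosome=markers_per_chromosome)
    pop = _polymorphic_panel(pop)
    arch = draw_architecture(
        np.arange(pop.n_markers), 100, 1.0, rng, h2=h2
    )
    y, _ = simulate_trait(pop, arch, rng)
    scheme = CVScheme(
        kind="single", training_populations=[pop.population_id],
        n_iterations=n_iterations, seed=int(rng.integers(2**31)),
    )
    return run_cv(scheme, method, {pop.population_id: (pop, y)})


def disjoint_architecture_null(seed: int = 0, n_reps: int = 50,
                               markers_per_chromosome: int = 40) -> dict:
    """Cross-population accuracy when training and validation traits share
    no QTLs at all.

    Each replicate draws 200 QTLs from the markers polymorphic in both
    populations, assigns disjoint halves to the two traits, trains on an
    80% sample of one population and evaluates on a 20% sample of the
    other.  By construction the expected accuracy is zero.
    """
    rng = as_rng(seed)
    pa, pb, _ = study_populations(seed=rng, markers_per_chromosome=markers_per_chromosome)
    pa, pb = intersect_markers([pa, pb])
    common = np.flatnonzero(pa.polymorphic_mask() & pb.polymorphic_mask())
    rs = []
    for _ in range(n_reps):
        both = draw_architecture(common, 200, 1.0, rng, h2=0.6)
        perm = rng.permutation(200)
        a_t = TraitArchitecture(both.qtl_marker_indices[perm[:100]], both.effects[perm[:100]], h2=0.6)
        a_v = TraitArchitecture(both.qtl_marker_indices[perm[100:]], both.effects[perm[100:]], h2=0.6)
        y_t, _ = simulate_trait(pa, a_t, rng)
        y_v, _ = simulate_trait(pb, a_v, rng)
        tr, _ = split_single(range(pa.n_lines), 0.8, rng)
        est = RidgeBLUP(h2=0.6).fit(pa.genotypes[tr], y_t[tr])
        sel = rng.choice(pb.n_lines, size=int(round(0.2 * pb.n_lines)), replace=False)
        rs.append(accuracy(est.predict(pb.genotypes[sel]), y_v[sel]))
    rs = np.asarray(rs)
    return {
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "se_r": float(rs.std(ddof=1) / np.sqrt(len(rs))),
        "n": n_reps,
    }


def qtl_sharing(seed: int = 0, n_reps: int = 50, method: str = "RIDGE"):
    """The cross-population shared-architecture experiment at full default
    population size (10 sharing fractions x h2 in {0.3, 0.6})."""
    rng = as_rng(seed)
    pa, pb, _ = study_populations(seed=rng)
    pa, pb = intersect_markers([pa, pb])
    return qtl_sharing_experiment(
        pa, pb, n_reps=n_reps, method=method, seed=int(rng.integers(2**31))
    )


def method_concordance(seed: int = 0, h2: float = 0.82, n_iterations: int = 15,
                       markers_per_chromosome: int = 60,
                       burn_in: int = 2000, n_iter: int = 7000) -> dict:
    """Single-population CV accuracy of all five prediction methods on the
    same simulated 100-QTL trait (shortened Gibbs chains)."""
    rng = as_rng(seed)
    pop, _, _ = study_populations(seed=rng, markers_per_chromosome=markers_per_chromosome)
    pop = _polymorphic_panel(pop)
    arch = draw_architecture(np.arange(pop.n_markers), 100, 1.0, rng, h2=h2)
    y, _ = simulate_trait(pop, arch, rng)
    cfg = GibbsConfig(h2_lambda=h2).scaled_down(burn_in, n_iter)
    methods = {
        "GBLUP": "GBLUP",
        "BRR": BayesianRidgeGEBV(config=cfg),
        "BLASSO": BayesianLassoGEBV(config=cfg),
        "RKHS": "RKHS",
        "RF": "RF",
    }
    out = {}
    for name, method in methods.items():
        scheme = CVScheme(
            kind="single", training_populations=[pop.population_id],
            n_iterations=n_iterations, seed=int(as_rng(seed).integers(2**31)),
        )
        res = run_cv(scheme, method, {pop.population_id: (pop, y)})
        out[name] = res.mean_r
    out["spread"] = float(max(out.values()) - min(v for k, v in out.items() if k != "spread"))
    return out


def phenotype_anova_recovery(seed: int = 0, n_reps: int = 200, n_lines: int = 300,
                             n_locations: int = 3, sigma2_g: float = 1.0,
                             sigma2_e: float = 1.0) -> dict:
    """Parameter recovery of the balanced across-location ANOVA: mean
    estimated variance components over replicated simulations."""
    import pandas as pd

    from .phenotype import anova_locations

    rng = as_rng(seed)
    est_g, est_e = [], []
    locs = [f"loc{l}" for l in range(n_locations)]
    lines = [f"L{i}" for i in range(n_lines)]
    for _ in range(n_reps):
        g = rng.normal(0, np.sqrt(sigma2_g), n_lines)
        rows = []
        for l in locs:
            e = rng.normal(0, np.sqrt(sigma2_e), n_lines)
            loc_eff = rng.normal(0, 1)
            rows.append(pd.DataFrame({"line": lines, "location": l, "value": g + loc_eff + e}))
        res = anova_locations(pd.concat(rows, ignore_index=True))
        est_g.append(res.sigma2_g)
        est_e.append(res.sigma2_e)
    return {
        "mean_sigma2_g": float(np.mean(est_g)),
        "mean_sigma2_e": float(np.mean(est_e)),
        "n": n_reps,
    }
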