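"""Prediction accuracy, cross-validation schemes, and the QTL-sharing experiment.

Accuracy is the Pearson correlation between GEBVs and observed phenotypes.
Three resampling schemes are provided:

* ``single`` — within one population, random 80/20 train/validation splits;
* ``composite`` — populations pooled first, then resampled as one;
* ``cross`` — 80% of the training population(s) fit the model, which is
  evaluated on a 20% sample of a held-out population.

Each iteration refits the model.  The QTL-sharing experiment simulates
traits in two populations whose architectures share a controlled fraction
of a common QTL set, and measures how cross-population accuracy decays as
sharing decreases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .io import MarkerMatrix
from .predictors import make_estimator
from .simulate import as_rng, draw_architecture, shared_subsets, simulate_trait

logger = logging.getLogger(__name__)


def accuracy(gebv, observed) -> float:
    """Pearson correlation between predicted and observed values.

    Returns NaN (with a warning) when either vector is constant, in which
    case the correlation is undefined.
    """
    gebv = np.asarray(gebv, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if gebv.shape != observed.shape:
        raise ValueError("gebv and observed differ in length")
    if len(gebv) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(gebv) == 0 or np.ptp(observed) == 0:
        warnings.warn("constant vector: accuracy undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(gebv, observed)[0, 1])


def split_single(line_ids, train_fraction: float, rng):
    """Random disjoint, exhaustive train/validation partition.

    Training size is ``round(train_fraction * n)``; the remainder validates.
    """
    rng = as_rng(rng)
    line_ids = list(line_ids)
    n = len(line_ids)
    if n < 5:
        raise ValueError("need at least 5 lines to split")
    n_train = int(round(train_fraction * n))
    if n_train <= 0 or n_train >= n:
        raise ValueError(f"train fraction {train_fraction} leaves an empty partition")
    perm = rng.permutation(n)
    train = [line_ids[i] for i in perm[:n_train]]
    valid = [line_ids[i] for i in perm[n_train:]]
    return train, valid


@dataclass
class CVScheme:
    """Cross-validation scheme specification."""

    kind: str
    training_populations: list
    validation_population: str | None = None
    train_fraction: float = 0.8
    n_iterations: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("single", "composite", "cross"):
            raise ValueError("kind must be single, composite or cross")
        if self.kind == "single" and len(self.training_populations) != 1:
            raise ValueError("single-population CV takes exactly one population")
        if self.kind == "composite" and len(self.training_populations) < 2:
            raise ValueError("composite CV needs at least two populations")
        if self.kind == "cross":
            if self.validation_population is None:
                raise ValueError("cross-population CV needs a validation population")
            if self.validation_population in self.training_populations:
                raise ValueError("validation population must be disjoint from training")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class CVResult:
    """Per-iteration accuracies with summary statistics."""

    per_iteration_r: np.ndarray
    scheme: CVScheme
    method: str
    trait: str = ""

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.per_iteration_r))

    @property
    def sd_r(self) -> float:
        return float(np.nanstd(self.per_iteration_r, ddof=1))

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.per_iteration_r).sum())

    def se_r(self) -> float:
        """Monte-Carlo standard error of the mean accuracy."""
        n = len(self.per_iteration_r) - self.n_undefined
        return self.sd_r / np.sqrt(max(n, 1))


def _check_harmonized(mats):
    ids0 = list(mats[0].marker_ids)
    for m in mats[1:]:
        if list(m.marker_ids) != ids0:
            raise ValueError(
                "populations are not marker-harmonized; run intersect_markers first"
            )


def _estimator_for(method, seed):
    if isinstance(method, str):
        est = make_estimator(method, seed=int(seed))
        name = method.upper()
    else:
        est = clone(method)
        name = type(method).__name__
    if "seed" in est.get_params():
        est.set_params(seed=int(seed))
    return est, name


def run_cv(scheme: CVScheme, method, populations: dict, trait: str = "") -> CVResult:
    """Run a cross-validation scheme.

    ``populations`` maps population id -> ``(MarkerMatrix, phenotypes)``
    with phenotypes aligned to the matrix's line order.  ``method`` is a
    method name (RIDGE/BRR/BLASSO/GBLUP/RKHS/RF) or an unfitted estimator
    used as a template (cloned and reseeded each iteration).  Every
    iteration refits the model on its training sample.
    """
    for pid in scheme.training_populations:
        if pid not in populations:
            raise KeyError(f"population {pid!r} not supplied")
    mats = [populations[p][0] for p in scheme.training_populations]
    if scheme.kind == "cross":
        mats = mats + [populations[scheme.validation_population][0]]
    _check_harmonized(mats)

    X_train_pool = np.vstack([populations[p][0].genotypes for p in scheme.training_populations])
    y_train_pool = np.concatenate(
        [np.asarray(populations[p][1], dtype=float) for p in scheme.training_populations]
    )
    n_pool = X_train_pool.shape[0]
    if scheme.kind == "cross":
        Xv = populations[scheme.validation_population][0].genotypes
        yv = np.asarray(populations[scheme.validation_population][1], dtype=float)

    ss = np.random.SeedSequence(scheme.seed)
    children = ss.spawn(scheme.n_iterations)
    rs = []
    for child in children:
        rng = np.random.default_rng(child)
        est_seed = rng.integers(2**31)
        est, name = _estimator_for(method, est_seed)
        tr, va = split_single(range(n_pool), scheme.train_fraction, rng)
        est.fit(X_train_pool[tr], y_train_pool[tr])
        if scheme.kind == "cross":
            # evaluate on a 20% sample of the held-out population
            n_va = max(3, int(round((1 - scheme.train_fraction) * len(yv))))
            sel = rng.choice(len(yv), size=n_va, replace=False)
            pred, obs = est.predict(Xv[sel]), yv[sel]
        else:
            pred, obs = est.predict(X_train_pool[va]), y_train_pool[va]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs.append(accuracy(pred, obs))
    rs = np.array(rs)
    n_nan = int(np.isnan(rs).sum())
    if n_nan:
        logger.warning("%d of %d iterations had undefined accuracy", n_nan, len(rs))
    return CVResult(per_iteration_r=rs, scheme=scheme, method=name, trait=trait)


def qtl_sharing_experiment(
    pop_train: MarkerMatrix,
    pop_valid: MarkerMatrix,
    fractions=None,
    h2_levels=(0.3, 0.6),
    method="RIDGE",
    n_qtl: int = 100,
    sigma_a: float = 1.0,
    n_reps: int = 50,
    seed: int = 0,
    scheme: str = "independent",
    overlap_subset_fraction: float = 0.5,
) -> pd.DataFrame:
    """Cross-population accuracy as a function of shared QTL architecture.

    For every sharing level and heritability: draw a 100-QTL additive
    architecture on the markers polymorphic in both populations, derive the
    two populations' (partially shared) architectures, simulate both traits,
    train on the full training population and predict the full validation
    population.  Repeated ``n_reps`` times per grid cell.

    ``scheme="independent"`` (default) draws each population's QTL subset
    of size ``round(fraction * n_qtl)`` independently, so the realized
    overlap proportion is about ``fraction`` of each subset.
    ``scheme="overlap"`` fixes the subset size and sets the shared
    proportion explicitly to ``fraction``.

    Returns a table with columns fraction, h2, mean_r, sd_r, se_r, n.
    """
    from .simulate import shared_subsets_overlap

    if fractions is None:
        fractions = np.round(np.arange(0.1, 1.01, 0.1), 2)
    _check_harmonized([pop_train, pop_valid])
    poly = pop_train.polymorphic_mask() & pop_valid.polymorphic_mask()
    common_idx = np.flatnonzero(poly)
    if len(common_idx) < n_qtl:
        raise ValueError(
            f"only {len(common_idx)} markers polymorphic in both populations; "
            f"need at least n_qtl={n_qtl}"
        )
    # common random numbers: each replicate reuses one seed across the whole
    # (fraction, h2) grid, so adjacent grid cells are paired comparisons and
    # curve differences reflect the sharing level, not replicate noise
    rep_children = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for h2 in h2_levels:
        for frac in fractions:
            cell = []
            for child in rep_children:
                rng = np.random.default_rng(child)
                arch = draw_architecture(common_idx, n_qtl, sigma_a, rng, h2=h2)
                if scheme == "independent":
                    # prefix of a uniform permutation == uniform draw without
                    # replacement; replaying the same replicate stream at each
                    # fraction nests the subsets so the curve is fully coupled
                    k = int(round(frac * n_qtl))
                    from .simulate import TraitArchitecture

                    pt, pv = rng.permutation(n_qtl), rng.permutation(n_qtl)
                    a_t = TraitArchitecture(
                        arch.qtl_marker_indices[pt[:k]], arch.effects[pt[:k]], h2=h2
                    )
                    a_v = TraitArchitecture(
                        arch.qtl_marker_indices[pv[:k]], arch.effects[pv[:k]], h2=h2
                    )
                else:
                    a_t, a_v = shared_subsets_overlap(
                        arch, overlap_subset_fraction, frac, rng
                    )
                y_t, _ = simulate_trait(pop_train, a_t, rng)
                y_v, _ = simulate_trait(pop_valid, a_v, rng)
                est, _ = _estimator_for(method, rng.integers(2**31))
                if "h2" in est.get_params():
                    est.set_params(h2=h2)
                est.fit(pop_train.genotypes, y_t)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cell.append(accuracy(est.predict(pop_valid.genotypes), y_v))
            cell = np.array(cell)
            n_ok = int(np.isfinite(cell).sum())
            rows.append(
                {
                    "fraction": float(frac),
                    "h2": float(h2),
                    "mean_r": float(np.nanmean(cell)),
                    "sd_r": float(np.nanstd(cell, ddof=1)),
                    "se_r": float(np.nanstd(cell, ddof=1) / np.sqrt(max(n_ok, 1))),
                    "n": n_ok,
                }
            )
    return pd.DataFrame(rows)
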