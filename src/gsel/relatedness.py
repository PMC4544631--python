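"""Marker-based kinship (IBS), diagonal normalization, group summaries and LD r2.

Kinship between fully inbred lines is estimated as the identity-by-state
proportion: the fraction of markers at which two lines carry the same 0/1
call.  Following common practice for coancestry reporting, a kinship matrix
may be rescaled by the mean of its diagonal so the diagonal averages 1.

Linkage disequilibrium between two markers is the squared Pearson
correlation of their 0/1 columns, which for fully inbred (homozygous) lines
equals the haplotype-based r2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MarkerMatrix


@dataclass
class KinshipMatrix:
    line_ids: list
    values: np.ndarray
    normalized: bool = False
    group_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match line ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix is not symmetric")
        if self.normalized and abs(np.mean(np.diag(self.values)) - 1.0) > 1e-9:
            raise ValueError("normalized kinship must have mean diagonal 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def ibs_kinship(m: MarkerMatrix, group_labels: dict | None = None) -> KinshipMatrix:
    """Identity-by-state kinship: proportion of markers with identical calls.

    Requires a complete (imputed) genotype matrix.  For 0/1 calls the
    matching proportion is ``(X X' + (1-X)(1-X)') / n_markers``; the
    diagonal is 1 for fully called lines.
    """
    if m.n_markers == 0:
        raise ValueError("no markers")
    X = m.genotypes
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; impute first")
    match = X @ X.T + (1.0 - X) @ (1.0 - X).T
    K = match / m.n_markers
    K = (K + K.T) / 2.0
    labels = dict(group_labels) if group_labels else (
        {l: m.population_id for l in m.line_ids} if m.population_id else {}
    )
    return KinshipMatrix(list(m.line_ids), K, normalized=False, group_labels=labels)


def combined_ibs_kinship(matrices) -> KinshipMatrix:
    """IBS kinship over lines pooled from several marker-harmonized matrices."""
    ids0 = matrices[0].marker_ids
    for m in matrices[1:]:
        if list(m.marker_ids) != list(ids0):
            raise ValueError("matrices are not marker-harmonized; intersect first")
    X = np.vstack([m.genotypes for m in matrices])
    lines = [l for m in matrices for l in m.line_ids]
    labels = {l: m.population_id for m in matrices for l in m.line_ids}
    pooled = MarkerMatrix(lines, list(ids0), X, population_id="", imputed=True)
    return ibs_kinship(pooled, group_labels=labels)


def normalize_kinship(k: KinshipMatrix) -> KinshipMatrix:
    """Divide every entry by the mean diagonal so the diagonal averages 1."""
    d = float(np.mean(np.diag(k.values)))
    if d <= 0:
        raise ValueError("mean diagonal must be positive to normalize")
    return replace(k, values=k.values / d, normalized=True)


def kinship_group_summary(k: KinshipMatrix) -> pd.DataFrame:
    """Mean/min/max off-diagonal kinship within and between groups.

    One row per unordered group pair; the diagonal is excluded from
    within-group statistics.
    """
    if not k.group_labels:
        raise ValueError("no group labels assigned")
    groups = {}
    for i, l in enumerate(k.line_ids):
        groups.setdefault(k.group_labels[l], []).append(i)
    names = sorted(groups)
    rows = []
    for ai, a in enumerate(names):
        for b in names[ai:]:
            ia, ib = np.array(groups[a]), np.array(groups[b])
            block = k.values[np.ix_(ia, ib)]
            if a == b:
                vals = block[np.triu_indices_from(block, k=1)]
            else:
                vals = block.ravel()
            if vals.size == 0:
                continue
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_pairs": int(vals.size),
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def ld_r2(a, b) -> float:
    """LD between two markers as the squared Pearson correlation of their
    0/1 columns over inbred lines (equivalent to haplotype r2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("marker columns differ in length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("marker columns contain missing values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a monomorphic marker")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_table(m: MarkerMatrix, pairs) -> pd.DataFrame:
    """r2 for a list of (marker_id_a, marker_id_b) pairs."""
    idx = {mid: j for j, mid in enumerate(m.marker_ids)}
    rows = []
    for a, b in pairs:
        rows.append(
            {
                "marker_a": a,
                "marker_b": b,
                "r2": ld_r2(m.genotypes[:, idx[a]], m.genotypes[:, idx[b]]),
            }
        )
    return pd.DataFrame(rows)
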