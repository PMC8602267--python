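"""Monte-Carlo chi-square tests for 2xK allele contingency tables.

Sparse multiallelic tables make the asymptotic chi-square reference
unreliable, so significance is assessed by simulation: null tables are
generated with the two row totals fixed and each row's column membership
drawn from the pooled marginal column probabilities.  Two statistics are
provided, following the CLUMP program's scheme:

T1
    Pearson chi-square of the full table.
T2
    Pearson chi-square after "clumping" — columns whose smaller expected
    cell falls below a threshold (default 5) are pooled into a single
    rare column.  The clumping rule is re-derived on every simulated
    table, so the reference distribution accounts for it.

The Monte-Carlo P is the (r+1)/(n+1) estimator, which never returns
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .data_model import ContingencyTable2xK, StrlinkError

T1 = "T1"
T2 = "T2"

DEFAULT_MIN_EXPECTED = 5.0
DEFAULT_N_SIM = 100_000

_TIE_EPS = 1e-9


class DegenerateTableError(StrlinkError):
    pass


def _drop_empty_columns(counts: np.ndarray, labels: list) -> tuple[np.ndarray, list]:
    keep = counts.sum(axis=0) > 0
    return counts[:, keep], [l for l, k in zip(labels, keep) if k]


def pearson_chi2(table: ContingencyTable2xK) -> float:
    """Pearson chi-square with expectations from product of margins;
    zero-total columns are dropped first."""
    counts, _ = _drop_empty_columns(table.counts, table.col_labels)
    if counts.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty columns")
    row = counts.sum(axis=1, keepdims=True)
    if (row == 0).any():
        raise DegenerateTableError("empty row in contingency table")
    return _chi2_counts(counts.astype(float))


def _chi2_counts(counts: np.ndarray) -> float:
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row * col / counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def collapse_small_columns(
    table: ContingencyTable2xK, min_expected: float = DEFAULT_MIN_EXPECTED
) -> tuple[ContingencyTable2xK, dict]:
    """Pool sparse columns into one "rare" column.

    A column is small when its smaller expected cell (= column total x
    smaller row total / grand total) is below ``min_expected``.  Small
    columns are pooled in ascending order of column total (ties broken by
    label) until the pooled column itself reaches the threshold or all
    small columns are pooled.  Returns the collapsed table and a map
    original column label -> collapsed column label.
    """
    counts, labels = _drop_empty_columns(table.counts, table.col_labels)
    if counts.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty columns")
    col_tot = counts.sum(axis=0)
    total = counts.sum()
    min_row = counts.sum(axis=1).min()
    small = col_tot * min_row / total < min_expected - _TIE_EPS

    collapse_map = {l: l for l in labels}
    if not small.any():
        out = ContingencyTable2xK(table.row_labels, list(labels), counts)
        return out, collapse_map

    order = sorted(
        (i for i in range(len(labels)) if small[i]),
        key=lambda i: (col_tot[i], str(labels[i])),
    )
    pooled_idx: list[int] = []
    pooled_total = 0
    for i in order:
        pooled_idx.append(i)
        pooled_total += col_tot[i]
        if pooled_total * min_row / total >= min_expected - _TIE_EPS:
            break

    keep = [i for i in range(len(labels)) if i not in pooled_idx]
    rare_label = "+".join(str(labels[i]) for i in pooled_idx)
    new_labels = [labels[i] for i in keep] + [rare_label]
    new_counts = np.column_stack(
        [counts[:, keep], counts[:, pooled_idx].sum(axis=1)]
    ) if keep else counts[:, pooled_idx].sum(axis=1, keepdims=True)
    if new_counts.shape[1] < 2:
        raise DegenerateTableError("all columns pooled into one")
    for i in pooled_idx:
        collapse_map[labels[i]] = rare_label
    return (
        ContingencyTable2xK(table.row_labels, new_labels, new_counts),
        collapse_map,
    )


def _collapse_counts_for_sim(counts: np.ndarray, min_expected: float) -> np.ndarray:
    """Clumping rule on a raw simulated count matrix (labels = indices).

    Degenerate outcomes (a single surviving column) return a 2x1 matrix,
    whose chi-square is 0 — the null-concordant limit.
    """
    keep_mask = counts.sum(axis=0) > 0
    counts = counts[:, keep_mask]
    if counts.shape[1] < 2:
        return counts
    col_tot = counts.sum(axis=0)
    total = counts.sum()
    min_row = counts.sum(axis=1).min()
    small = col_tot * min_row / total < min_expected - _TIE_EPS
    if not small.any():
        return counts
    order = sorted(np.flatnonzero(small), key=lambda i: (col_tot[i], i))
    pooled: list[int] = []
    pooled_total = 0
    for i in order:
        pooled.append(i)
        pooled_total += col_tot[i]
        if pooled_total * min_row / total >= min_expected - _TIE_EPS:
            break
    keep = [i for i in range(counts.shape[1]) if i not in pooled]
    if keep:
        return np.column_stack([counts[:, keep], counts[:, pooled].sum(axis=1)])
    return counts[:, pooled].sum(axis=1, keepdims=True)


@dataclass
class ClumpResult:
    statistic: str
    chi2_obs: float
    k_effective: int
    collapse_map: dict
    n_sim: int
    n_exceed: int
    p_mc: float
    seed: int

    def __post_init__(self):
        if not 0 < self.p_mc <= 1:
            raise StrlinkError(f"p_mc {self.p_mc} outside (0, 1]")


def clump_test(
    table: ContingencyTable2xK,
    statistic: str = T1,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 1,
    min_expected: float = DEFAULT_MIN_EXPECTED,
) -> ClumpResult:
    """Monte-Carlo significance of a 2xK table under fixed row totals.

    Null tables draw each row from Multinomial(row total, pooled column
    probabilities).  For T2 the clumping rule is re-derived on each
    simulated table.  Deterministic given ``seed``.
    """
    if statistic not in (T1, T2):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")

    counts, labels = _drop_empty_columns(table.counts, table.col_labels)
    if counts.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty columns")

    if statistic == T1:
        chi2_obs = pearson_chi2(table)
        k_eff = counts.shape[1]
        collapse_map = {l: l for l in labels}
    else:
        collapsed, collapse_map = collapse_small_columns(
            ContingencyTable2xK(table.row_labels, list(labels), counts), min_expected
        )
        chi2_obs = pearson_chi2(collapsed)
        k_eff = len(collapsed.col_labels)

    rng = np.random.default_rng(seed)
    row_tot = counts.sum(axis=1)
    p_cols = counts.sum(axis=0) / counts.sum()

    sims1 = rng.multinomial(row_tot[0], p_cols, size=n_sim)
    sims2 = rng.multinomial(row_tot[1], p_cols, size=n_sim)

    if statistic == T1:
        chi2_sim = _chi2_batch(sims1, sims2)
        n_exceed = int((chi2_sim >= chi2_obs - _TIE_EPS).sum())
    else:
        n_exceed = 0
        for r1, r2 in zip(sims1, sims2):
            sim_counts = np.vstack([r1, r2])
            collapsed_counts = _collapse_counts_for_sim(sim_counts, min_expected)
            chi2 = _chi2_counts(collapsed_counts.astype(float)) if collapsed_counts.shape[1] > 1 else 0.0
            if chi2 >= chi2_obs - _TIE_EPS:
                n_exceed += 1

    return ClumpResult(
        statistic=statistic,
        chi2_obs=chi2_obs,
        k_effective=k_eff,
        collapse_map=collapse_map,
        n_sim=n_sim,
        n_exceed=n_exceed,
        p_mc=(n_exceed + 1) / (n_sim + 1),
        seed=seed,
    )


def _chi2_batch(rows1: np.ndarray, rows2: np.ndarray) -> np.ndarray:
    """Vectorised Pearson chi-square for a batch of 2xK tables."""
    counts = np.stack([rows1, rows2], axis=1).astype(float)  # (n, 2, K)
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    total = counts.sum(axis=(1, 2), keepdims=True)
    expected = row * col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=(1, 2))
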