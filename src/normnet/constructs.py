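"""From raw norm items to latent descriptive and injunctive scores.

Raw Likert items from the self-report survey and the incentivized
coordination game are first aligned onto a common [0, 1] scale (0 = against
smoking, 1 = favorable toward smoking), reverse-coding items whose raw
direction runs the other way. Items are then averaged into constructs
(omitting "I don't have one" relationships), each construct's internal
reliability is summarized with Cronbach's alpha, and a one-factor
measurement model per norm type (descriptive, injunctive) yields a single
latent score per student per wave, min-max rescaled to [0, 1].

Scale alignment uses the affine map (x - min) / (max - min) after
reverse-coding, so the scale endpoints land exactly on 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .data import (
    INC_INJUNCTIVE_SUBGROUPS,
    ITEM_FAMILIES,
    WAVES,
    item_columns,
)

__all__ = [
    "ItemBlock",
    "standardize_block",
    "aggregate_relationship_mean",
    "cronbach_alpha",
    "fit_one_factor",
    "build_norm_scores",
]


@dataclass
class ItemBlock:
    """A students x items matrix with its scale declaration.

    ``high_is_favorable`` flags, per item, whether a high raw value means
    favorable toward smoking. ``na_code`` (e.g. the "I don't have one"
    option) is converted to missing during standardization.
    """

    name: str
    values: np.ndarray  # students x items, NaN = missing
    scale_min: np.ndarray
    scale_max: np.ndarray
    high_is_favorable: np.ndarray
    na_code: float | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.values.shape[1]
        self.scale_min = np.broadcast_to(np.asarray(self.scale_min, float), (k,)).copy()
        self.scale_max = np.broadcast_to(np.asarray(self.scale_max, float), (k,)).copy()
        self.high_is_favorable = np.broadcast_to(
            np.asarray(self.high_is_favorable, bool), (k,)
        ).copy()
        if (self.scale_max <= self.scale_min).any():
            raise ValueError("scale maxima must exceed minima")


def standardize_block(block: ItemBlock) -> ItemBlock:
    """Align every item onto [0, 1] with 1 = favorable toward smoking."""
    if block.standardized:
        return block
    vals = block.values.copy()
    if block.na_code is not None:
        vals[vals == block.na_code] = np.nan
    lo, hi = block.scale_min, block.scale_max
    with np.errstate(invalid="ignore"):
        below = vals < lo
        above = vals > hi
    if below.any() or above.any():
        i, j = np.argwhere(below | above)[0]
        raise ValueError(
            f"block {block.name!r}: value {vals[i, j]} outside "
            f"[{lo[j]}, {hi[j]}] at row {i}, item {j}"
        )
    std = (vals - lo) / (hi - lo)
    std[:, ~block.high_is_favorable] = 1.0 - std[:, ~block.high_is_favorable]
    return replace(
        block,
        values=std,
        scale_min=np.zeros_like(lo),
        scale_max=np.ones_like(hi),
        high_is_favorable=np.ones_like(block.high_is_favorable),
        na_code=None,
        standardized=True,
    )


def aggregate_relationship_mean(block: ItemBlock) -> np.ndarray:
    """Per-student mean over the non-missing items of a standardized block."""
    if not block.standardized:
        raise ValueError("aggregate expects a standardized block")
    with np.errstate(invalid="ignore"):
        return np.nanmean(block.values, axis=1)


def cronbach_alpha(block: ItemBlock) -> float:
    """Internal-consistency reliability on complete rows.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total).
    Returns NaN when the total score has no variance.
    """
    vals = block.values
    if vals.shape[1] < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    complete = vals[~np.isnan(vals).any(axis=1)]
    if complete.shape[0] < 3:
        raise ValueError("Cronbach's alpha needs at least 3 complete rows")
    k = complete.shape[1]
    item_var = complete.var(axis=0, ddof=1).sum()
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def fit_one_factor(constructs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-factor measurement model by maximum likelihood.

    Returns (loadings, scores): scores are posterior factor means (the
    regression method), oriented so the loading sum is positive and affinely
    rescaled to [0, 1] over the sample.
    """
    x = np.asarray(constructs, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 construct columns")
    if np.isnan(x).any():
        raise ValueError("one-factor model expects complete rows only")
    cov = np.cov(x, rowvar=False)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 1e-12:
        degenerate = [int(i) for i in np.argwhere(np.isclose(np.diag(cov), 0)).ravel()]
        raise ValueError(
            "construct covariance is not positive definite"
            + (f" (zero-variance columns {degenerate})" if degenerate else "")
        )
    fa = FactorAnalysis(n_components=1, svd_method="lapack")
    scores = fa.fit_transform(x).ravel()
    loadings = fa.components_.ravel()
    if loadings.sum() < 0:
        loadings, scores = -loadings, -scores
    span = scores.max() - scores.min()
    if span > 0:
        scores = (scores - scores.min()) / span
    else:
        scores = np.full_like(scores, 0.5)
    return loadings, scores


# --------------------------------------------------------------------------
# pipeline assembly


def _blocks_from_table(table: pd.DataFrame, wave: str) -> dict[str, ItemBlock]:
    blocks = {}
    for fam in ITEM_FAMILIES:
        cols = item_columns(fam, wave)
        blocks[fam.name] = ItemBlock(
            name=f"{fam.name}_{wave}",
            values=table[cols].to_numpy(dtype=float),
            scale_min=fam.scale_min,
            scale_max=fam.scale_max,
            high_is_favorable=fam.high_is_favorable,
        )
    return blocks


def _construct_matrix(blocks: dict[str, ItemBlock], kind: str) -> tuple[np.ndarray, list]:
    """Aggregate standardized item blocks into construct columns."""
    std = {name: standardize_block(b) for name, b in blocks.items()}
    cols, names = [], []
    if kind == "descriptive":
        for name in ("sr_descriptive_family", "sr_descriptive_peer", "inc_descriptive"):
            cols.append(aggregate_relationship_mean(std[name]))
            names.append(name)
    elif kind == "injunctive":
        cols.append(aggregate_relationship_mean(std["sr_injunctive"]))
        names.append("sr_injunctive")
        inc = std["inc_injunctive"].values
        for sub, idx in INC_INJUNCTIVE_SUBGROUPS.items():
            with np.errstate(invalid="ignore"):
                cols.append(np.nanmean(inc[:, list(idx)], axis=1))
            names.append(sub)
    else:
        raise ValueError(kind)
    return np.column_stack(cols), names


def build_norm_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Latent descriptive and injunctive scores per student per wave.

    Returns a frame with columns ``school, student, wave, descriptive,
    injunctive, complete``; ``complete`` is True only for students with both
    scores at both waves (the complete-case analysis set). The measurement
    model is fitted per wave on students with complete constructs at that
    wave.
    """
    waves_present = set(table["wave"])
    if set(WAVES) - waves_present:
        raise ValueError(f"attribute table lacks waves: {sorted(set(WAVES) - waves_present)}")
    pieces = []
    for wave in WAVES:
        sub = table[table["wave"] == wave].reset_index(drop=True)
        blocks = _blocks_from_table(sub, wave)
        out = sub[["school", "student"]].copy()
        out["wave"] = wave
        for kind in ("descriptive", "injunctive"):
            matrix, _ = _construct_matrix(blocks, kind)
            ok = ~np.isnan(matrix).any(axis=1)
            scores = np.full(len(sub), np.nan)
            if ok.sum() >= 3:
                _, scores_ok = fit_one_factor(matrix[ok])
                scores[ok] = scores_ok
            out[kind] = scores
        pieces.append(out)
    scores = pd.concat(pieces, ignore_index=True)
    ok = scores[["descriptive", "injunctive"]].notna().all(axis=1)
    n_waves_ok = ok.groupby([scores["school"], scores["student"]]).transform("sum")
    scores["complete"] = n_waves_ok == len(WAVES)
    return scores
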