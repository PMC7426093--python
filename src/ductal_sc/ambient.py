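"""Cell calling and ambient-RNA ("soup") estimation and correction.

Droplet data contain cell-free transcripts that contaminate every droplet.
The model here is deliberately simple and fully deterministic:

* valid cells are barcodes in an inclusive total-UMI band (default
  350..15,000);
* empty droplets are selected per sample from a configured inclusive
  total-UMI range;
* the soup profile of a sample is the pooled gene-fraction vector of its
  empty droplets;
* the contamination budget of a sample is the modal total-UMI count m of
  its empty droplets — the same number of ambient molecules is assumed to
  enter every droplet, so a cell with n total UMIs has contamination
  fraction rho = min(1, m / n);
* correction removes round(rho * n) counts per cell: first the rounded
  per-gene expected soup counts (clamped at the observed counts), then the
  remainder one count at a time from the gene with the largest remaining
  soup-excess ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, SoupModel

logger = logging.getLogger(__name__)


def call_cells(counts: CountMatrix, min_umis: int = 350,
               max_umis: int = 15_000) -> list[str]:
    """Barcodes whose total UMI count lies in [min_umis, max_umis] (inclusive)."""
    totals = counts.totals()
    keep = (totals >= min_umis) & (totals <= max_umis)
    return [b for b, k in zip(counts.barcodes, keep) if k]


def select_empty_droplets(counts: CountMatrix,
                          range_per_sample: dict[str, tuple[int, int]]
                          ) -> list[str]:
    """Barcodes whose totals fall in their sample's inclusive [lo, hi] range."""
    for s in np.unique(counts.sample_of):
        if s not in range_per_sample:
            raise ValueError(f"no empty-droplet range configured for sample {s!r}")
    totals = counts.totals()
    out = []
    for b, s, t in zip(counts.barcodes, counts.sample_of, totals):
        lo, hi = range_per_sample[s]
        if lo <= t <= hi:
            out.append(b)
    return out


def estimate_soup_profile(counts: CountMatrix,
                          empty: list[str]) -> dict[str, np.ndarray]:
    """Pooled gene-fraction profile of the empty droplets, per sample."""
    if not empty:
        raise ValueError("empty-droplet set is empty")
    bidx = counts.barcode_index()
    cols = np.array([bidx[b] for b in empty], dtype=int)
    profiles: dict[str, np.ndarray] = {}
    for s in np.unique(counts.sample_of[cols]):
        scols = cols[counts.sample_of[cols] == s]
        pooled = np.asarray(counts.X[:, scols].sum(axis=1)).ravel().astype(float)
        tot = pooled.sum()
        if tot == 0:
            raise ValueError(f"empty droplets of sample {s!r} contain no counts")
        profiles[s] = pooled / tot
    return profiles


def _estimate_mode(values: np.ndarray, window: int | None = None) -> int:
    """Mode of an integer sample via a lightly smoothed histogram.

    The raw sample mode of a dispersed unimodal count distribution is
    unstable, so the histogram is smoothed with a moving average before
    taking the argmax.  The default window is sqrt(mean) rounded to odd —
    the Poisson-scale bandwidth — and ``window=1`` gives the raw mode.
    Ties resolve toward the smaller value (conservative removal).
    """
    lo = int(values.min())
    hist = np.bincount(values.astype(int) - lo).astype(float)
    if window is None:
        window = max(1, int(round(np.sqrt(values.mean()))))
        window += (window + 1) % 2
    if window > 1:
        hist = np.convolve(hist, np.ones(window) / window, mode="same")
    top = hist == hist.max()
    if top.sum() > 1:
        logger.warning("multimodal empty-droplet histogram; using smallest mode")
    return lo + int(np.argmax(hist))


def estimate_rho(counts: CountMatrix, empty: list[str],
                 valid: list[str],
                 mode_smooth_window: int | None = None) -> SoupModel:
    """Estimate per-sample soup profiles, modal empty totals and per-cell rho.

    The modal total-UMI count m of a sample's empty droplets is taken as a
    fixed ambient budget per droplet; a valid cell with n total UMIs gets
    rho = min(1, m / n).
    """
    if not empty or not valid:
        raise ValueError("both empty and valid barcode sets must be nonempty")
    profiles = estimate_soup_profile(counts, empty)
    bidx = counts.barcode_index()
    totals = counts.totals()

    ecols = np.array([bidx[b] for b in empty], dtype=int)
    modal: dict[str, int] = {}
    for s in np.unique(counts.sample_of[ecols]):
        scols = ecols[counts.sample_of[ecols] == s]
        modal[s] = _estimate_mode(totals[scols], mode_smooth_window)

    rho = {}
    for b in valid:
        c = bidx[b]
        s = counts.sample_of[c]
        if s not in modal:
            raise ValueError(f"no empty droplets for sample {s!r} of cell {b!r}")
        n_c = totals[c]
        rho[b] = min(1.0, modal[s] / n_c) if n_c > 0 else 0.0
    return SoupModel(soup_profile=profiles, modal_empty_umis=modal,
                     rho_per_cell=pd.Series(rho))


def _remove_greedy(col: np.ndarray, e: np.ndarray, target: int) -> np.ndarray:
    """Clamped rounding, then one count at a time by largest soup-excess
    ratio e_g / (remaining_g + 1)."""
    removed = np.minimum(col, np.round(e).astype(np.int64))
    remaining = col - removed
    deficit = target - int(removed.sum())
    while deficit > 0 and remaining.sum() > 0:
        ratio = np.where(remaining > 0, e / (remaining + 1.0), -np.inf)
        g = int(np.argmax(ratio))
        remaining[g] -= 1
        deficit -= 1
    return remaining


def _remove_sampled(col: np.ndarray, e: np.ndarray, target: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Clamped flooring, then a seeded proportional draw of the remainder.

    The continuous target per gene is t_g = min(observed_g, e_g); its floor
    is removed outright and the residual removal mass is drawn
    multinomially with weights given by the fractional parts (falling back
    to the soup expectation when those are exhausted), clipped at the
    remaining counts.  Sampling decorrelates the sub-integer removals
    across cells, so pooled removals track the expected soup without the
    systematic bias a deterministic rounding rule imposes.
    """
    t = np.minimum(col.astype(float), e)
    base = np.floor(t).astype(np.int64)
    remaining = col - base
    deficit = target - int(base.sum())
    frac = t - base
    while deficit > 0 and remaining.sum() > 0:
        w = np.where(remaining > 0, frac, 0.0)
        if w.sum() <= 1e-12:
            w = np.where(remaining > 0, e, 0.0)
        if w.sum() <= 1e-12:
            w = (remaining > 0).astype(float)
        draw = rng.multinomial(deficit, w / w.sum())
        take = np.minimum(draw, remaining)
        remaining -= take
        deficit -= int(take.sum())
        frac = np.where(take > 0, 0.0, frac)
    return remaining


def adjust_counts(counts: CountMatrix, soup: SoupModel,
                  method: str = "sampled", seed: int = 0) -> CountMatrix:
    """Remove the estimated ambient contribution from each valid cell.

    For a cell with total n and contamination fraction rho, the removal
    target is T = round(rho * n) and the expected soup count of gene g is
    e_g = rho * n * soup_g.  ``method="sampled"`` (default) removes
    floor(min(observed, e)) per gene and allocates the remainder by a
    seeded proportional draw; ``method="greedy"`` removes
    min(observed, round(e)) per gene and the remainder one count at a time
    from the gene with the largest ratio e_g / (remaining_g + 1).  Both
    are deterministic for fixed inputs (and seed), integral, elementwise
    bounded by the input, and remove exactly T counts whenever the cell
    has that many.  Barcodes without a rho entry pass through untouched.
    """
    if method not in ("sampled", "greedy"):
        raise ValueError(f"unknown adjustment method {method!r}")
    rng = np.random.default_rng(seed)
    dense = counts.to_dense().astype(np.int64)
    bidx = counts.barcode_index()
    for b, rho_c in soup.rho_per_cell.items():
        if rho_c == 0:
            continue
        c = bidx[b]
        col = dense[:, c]
        n_c = col.sum()
        if n_c == 0:
            continue
        prof = soup.soup_profile[counts.sample_of[c]]
        e = rho_c * n_c * prof
        target = int(round(rho_c * n_c))
        if method == "greedy":
            dense[:, c] = _remove_greedy(col, e, target)
        else:
            dense[:, c] = _remove_sampled(col, e, target, rng)
    return CountMatrix(genes=list(counts.genes), barcodes=list(counts.barcodes),
                       X=sp.csr_matrix(dense), sample_of=counts.sample_of.copy())
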