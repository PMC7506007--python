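"""ABBA-BABA D and fd admixture-proportion statistics in sliding windows.

Given derived-allele frequencies p1, p2, p3, pO in populations P1, P2, P3 and
an outgroup O (topology (((P1, P2), P3), O)), excess sharing of derived
alleles between P2 and P3 indicates introgression.  The frequency-based site
components are

    ABBA = (1 - p1) * p2 * p3 * (1 - pO)
    BABA = p1 * (1 - p2) * p3 * (1 - pO)

and the window statistics are D = sum(ABBA - BABA) / sum(ABBA + BABA), and the
admixture proportion fd, which normalises the same numerator by its value
under complete introgression from the donor: the donor frequency
pD = max(p2, p3) replaces both p2 and p3 in the denominator components.  fd is
defined only in windows with D > 0 and a positive denominator (it estimates a
proportion of the genome shared through gene flow and is meaningless where
there is no excess sharing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FREQ_COLS = ["p1", "p2", "p3", "pO"]


def site_components(p1, p2, p3, pO) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (abba, baba, abba_donor, baba_donor) components, vectorised."""
    p1, p2, p3, pO = (np.asarray(x, dtype=float) for x in (p1, p2, p3, pO))
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    pd_ = np.maximum(p2, p3)
    abba_d = (1 - p1) * pd_ * pd_ * (1 - pO)
    baba_d = p1 * (1 - pd_) * pd_ * (1 - pO)
    return abba, baba, abba_d, baba_d


def repolarize(freqs: pd.DataFrame) -> pd.DataFrame:
    """Flip sites where the outgroup frequency exceeds 0.5.

    The outgroup defines the ancestral allele; where pO > 0.5 the labelled
    allele is the ancestral one, so all four frequencies are mirrored.
    """
    f = freqs.copy()
    flip = f["pO"] > 0.5
    f.loc[flip, FREQ_COLS] = 1.0 - f.loc[flip, FREQ_COLS]
    return f


def fd_windows(freqs: pd.DataFrame, window_bp: int = 100_000,
               step_bp: int | None = None, min_sites: int = 100) -> pd.DataFrame:
    """D and fd in sliding windows.

    ``freqs`` columns: chrom, pos, p1, p2, p3, pO (sorted positions).  The
    default step is window/5 (overlapping windows).  Windows with fewer than
    ``min_sites`` sites, D <= 0 or a non-positive denominator get fd = NaN.
    """
    if freqs.empty:
        raise ValueError("empty frequency table")
    if step_bp is None:
        step_bp = max(window_bp // 5, 1)
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    bad = ~freqs[FREQ_COLS].apply(lambda c: c.between(0, 1)).all(axis=1)
    if bad.any():
        raise ValueError("frequencies must lie in [0, 1]")
    freqs = repolarize(freqs)
    rows = []
    for chrom, sub in freqs.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        abba, baba, abba_d, baba_d = site_components(
            sub["p1"], sub["p2"], sub["p3"], sub["pO"])
        last = pos.max()
        for start in range(0, int(last) + 1, step_bp):
            end = start + window_bp
            # pos is 1-based; window [start, end) covers pos in (start, end]
            i0 = np.searchsorted(pos, start + 1, side="left")
            i1 = np.searchsorted(pos, end, side="right")
            n = i1 - i0
            num = abba[i0:i1].sum() - baba[i0:i1].sum()
            tot = abba[i0:i1].sum() + baba[i0:i1].sum()
            den = abba_d[i0:i1].sum() - baba_d[i0:i1].sum()
            D = num / tot if tot > 0 else np.nan
            if n < min_sites or not np.isfinite(D) or D <= 0 or den <= 0:
                fd = np.nan
            else:
                fd = num / den
            rows.append((chrom, start, end, int(n), D, fd))
            if start + step_bp > last:
                break
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "D", "fd"])
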