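"""Chromosome-integrity checks from per-base depth tracks.

Depth tracks (samtools-depth dialect: chrom, 1-based position, depth)
are reduced to mean depth per tiling window (default 10 kb), and the
polyploid-vs-parent window ratio flags lost or under-covered regions:
an intact chromosome keeps ratios near 1 along its whole length, while
a missing chromosome yields zero coverage in the polyploid track.

Coordinates are 0-based half-open internally; the 1-based input dialect
is converted at the boundary.  Bases absent from a track count as depth
0, and the final partial window is averaged over its actual width.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError

DEFAULT_WINDOW_SIZE = 10_000
DEFAULT_LOW_RATIO = 0.25


def _windows_for_chrom(
    pos: np.ndarray, depth: np.ndarray, length: int, window_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window (start, end, mean depth) arrays tiling [0, length)."""
    n_win = max(1, int(np.ceil(length / window_size)))
    starts = np.arange(n_win, dtype=np.int64) * window_size
    ends = np.minimum(starts + window_size, length)
    sums = np.bincount((pos - 1) // window_size, weights=depth, minlength=n_win)
    widths = (ends - starts).astype(float)
    return starts, ends, sums[:n_win] / widths


def window_means(
    depth: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean depth per tiling window for every chromosome in the track.

    Positions must be sorted (strictly increasing) within a chromosome.
    Chromosome length is taken from ``chrom_lengths`` when given, else
    inferred from the maximum observed position.
    """
    if window_size <= 0:
        raise InvalidParameterError("window_size must be > 0")
    frames = []
    for chrom, grp in depth.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise FormatError(f"{chrom}: positions must be sorted and unique")
        length = int(chrom_lengths.get(chrom, pos[-1])) if chrom_lengths else int(pos[-1])
        if pos[-1] > length:
            raise FormatError(
                f"{chrom}: position {pos[-1]} exceeds declared length {length}"
            )
        starts, ends, means = _windows_for_chrom(
            pos, grp["depth"].to_numpy(dtype=float), length, window_size
        )
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "mean_depth": means}
            )
        )
    if not frames:
        raise FormatError("depth track contains no rows")
    return pd.concat(frames, ignore_index=True)


def depth_ratio(
    numerator: pd.DataFrame,
    denominator: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW_SIZE,
    scale_normalize: bool = False,
    low_threshold: float = DEFAULT_LOW_RATIO,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window depth ratio numerator/denominator across both tracks.

    With ``scale_normalize`` each track's window means are first divided
    by its genome-wide mean depth (library-size correction; off by
    default, matching a plain coverage ratio).  A chromosome present in
    only one track is reported with every window flagged missing on the
    absent side rather than raising.
    """
    win_num = window_means(numerator, window_size, chrom_lengths)
    win_den = window_means(denominator, window_size, chrom_lengths)
    if scale_normalize:
        for win in (win_num, win_den):
            widths = (win["end"] - win["start"]).to_numpy(dtype=float)
            total = float((win["mean_depth"].to_numpy() * widths).sum())
            genome_mean = total / float(widths.sum())
            if genome_mean <= 0:
                raise InvalidParameterError(
                    "cannot scale-normalize a track with zero genome-wide depth"
                )
            win["mean_depth"] = win["mean_depth"] / genome_mean

    num_by_chrom = dict(tuple(win_num.groupby("chrom", sort=False)))
    den_by_chrom = dict(tuple(win_den.groupby("chrom", sort=False)))
    chroms = sorted(set(num_by_chrom) | set(den_by_chrom))
    rows = []
    for chrom in chroms:
        wn = num_by_chrom.get(chrom)
        wd = den_by_chrom.get(chrom)
        template = wn if wn is not None else wd
        starts = template["start"].to_numpy()
        ends = template["end"].to_numpy()
        mean_n = wn["mean_depth"].to_numpy() if wn is not None else np.zeros(len(starts))
        mean_d = wd["mean_depth"].to_numpy() if wd is not None else np.zeros(len(starts))
        if wn is not None and wd is not None and len(wn) != len(wd):
            # same chromosome, different observed extents: align on the longer tiling
            k = max(len(wn), len(wd))
            longer = wn if len(wn) == k else wd
            starts, ends = longer["start"].to_numpy(), longer["end"].to_numpy()
            mean_n = np.pad(wn["mean_depth"].to_numpy(), (0, k - len(wn)))
            mean_d = np.pad(wd["mean_depth"].to_numpy(), (0, k - len(wd)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mean_d > 0, mean_n / np.where(mean_d > 0, mean_d, 1), np.nan)
        status = np.where(
            mean_d == 0,
            "missing_den",
            np.where(mean_n == 0, "missing_num", np.where(ratio < low_threshold, "low", "ok")),
        )
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "mean_depth_num": mean_n,
                    "mean_depth_den": mean_d,
                    "ratio": ratio,
                    "status": status,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def chromosome_verdict(
    ratios: pd.DataFrame, min_ok_fraction: float = 0.9
) -> dict[str, dict]:
    """Per-chromosome integrity verdict from a window-ratio table.

    A chromosome is 'intact' when at least ``min_ok_fraction`` of its
    windows have status ok, 'missing' when none of its windows has
    numerator coverage, else 'degraded'.
    """
    out: dict[str, dict] = {}
    for chrom, grp in ratios.groupby("chrom", sort=True):
        n = len(grp)
        n_ok = int((grp["status"] == "ok").sum())
        frac_ok = n_ok / n
        if (grp["mean_depth_num"] == 0).all():
            verdict = "missing"
        elif frac_ok >= min_ok_fraction:
            verdict = "intact"
        else:
            verdict = "degraded"
        out[chrom] = {
            "n_windows": n,
            "n_ok": n_ok,
            "fraction_ok": frac_ok,
            "verdict": verdict,
        }
    return out
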