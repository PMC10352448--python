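"""Reading and writing the package's delimited formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import TrajectoryPanel
from .temporal import TemporalSample

__all__ = [
    "panel_to_frame",
    "panel_to_counts_frame",
    "read_temporal_csv",
    "temporal_sample_from_counts",
]

COUNTS_COLUMNS = ["time_point", "subpop", "locus", "allele_A_count", "sample_size_diploid"]


def panel_to_frame(panel: TrajectoryPanel) -> pd.DataFrame:
    """Long-format frequencies: checkpoint, subpop (1-based), locus, freq."""
    k, s, L = panel.frequencies.shape
    rows = {
        "checkpoint": np.repeat(panel.checkpoints, s * L),
        "subpop": np.tile(np.repeat(np.arange(1, s + 1), L), k),
        "locus": np.tile(np.arange(1, L + 1), k * s),
        "freq": panel.frequencies.ravel(),
    }
    return pd.DataFrame(rows)


def panel_to_counts_frame(panel: TrajectoryPanel, Nc: np.ndarray, t: int, tau: int) -> pd.DataFrame:
    """Full-census counts table for the two sampling checkpoints, in the
    layout the temporal estimator consumes."""
    frames = []
    for label, gen in (("0", t), ("tau", t + tau)):
        f = panel.at(gen)  # (s, L)
        s, L = f.shape
        twoNc = (2 * np.asarray(Nc)).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "time_point": label,
                    "subpop": np.repeat(np.arange(1, s + 1), L),
                    "locus": np.tile(np.arange(1, L + 1), s),
                    "allele_A_count": np.round(
                        (f * twoNc[:, None]).ravel()
                    ).astype(np.int64),
                    "sample_size_diploid": np.repeat(np.asarray(Nc, dtype=float), L),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def temporal_sample_from_counts(df: pd.DataFrame, tau: int) -> TemporalSample:
    """Build a TemporalSample from a long counts table with columns
    time_point in {0, tau}, subpop, locus, allele_A_count,
    sample_size_diploid."""
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table is missing columns: {sorted(missing)}")
    df = df.copy()
    df["time_point"] = df["time_point"].astype(str)
    subpops = sorted(df["subpop"].unique())
    loci = sorted(df["locus"].unique())
    shape = (len(loci), len(subpops))

    def pivot(tp: str, col: str, fill=np.nan) -> np.ndarray:
        sub = df[df["time_point"] == tp]
        table = sub.pivot_table(index="locus", columns="subpop", values=col, aggfunc="first")
        table = table.reindex(index=loci, columns=subpops)
        out = table.to_numpy(dtype=float)
        if out.shape != shape:
            raise ValueError("counts table is not rectangular")
        return out

    freqs, sizes = {}, {}
    for tp in ("0", "tau"):
        cnt = pivot(tp, "allele_A_count")
        n = pivot(tp, "sample_size_diploid")
        freqs[tp] = cnt / (2.0 * n)
        sizes[tp] = n
    return TemporalSample(
        p_t=freqs["0"],
        p_t_tau=freqs["tau"],
        n_t=np.nanmean(sizes["0"], axis=0),
        n_t_tau=np.nanmean(sizes["tau"], axis=0),
        tau=tau,
    )


def read_temporal_csv(path, tau: int) -> TemporalSample:
    return temporal_sample_from_counts(pd.read_csv(path), tau)
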