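"""Footprint quality control: length histogram, metagene profiles,
A-site offset calibration, and reading-frame periodicity.

The metagene convention: positions are signed nt relative to the first
nucleotide of the start codon (anchor ``"start"``) or of the stop codon
(anchor ``"stop"``); position 0 is the anchor nucleotide itself.  An
initiating ribosome protects the start codon in its P-site, so with a
length-l footprint whose A-site offset is ``d_l`` the 5'-end peak sits at
``3 - d_l`` (the A-site is codon 2, i.e. +3 nt): offsets are recovered from
the peak as ``offset = 3 - p*``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, OffsetTable

__all__ = [
    "MetageneProfile",
    "FrameReport",
    "length_histogram",
    "metagene_profile",
    "calibrate_offsets",
    "frame_report",
    "plot_length_histogram",
    "plot_metagene",
    "plot_frame_report",
]

logger = logging.getLogger("riboage.qc")


def length_histogram(reads: pd.DataFrame) -> Dict[int, int]:
    """Read-length histogram over all reads (empty input -> empty dict)."""
    if len(reads) == 0:
        return {}
    counts = reads["length"].value_counts().sort_index()
    return {int(k): int(v) for k, v in counts.items()}


@dataclass
class MetageneProfile:
    """Summed 5'-end counts by signed position, stratified by read length.

    ``table`` has columns ``length, position, count``; ``n_in_window`` and
    ``n_out_window`` partition the reads considered (mass conservation:
    their sum equals the number of contributing reads).
    """

    anchor: str
    window: Tuple[int, int]
    table: pd.DataFrame
    n_in_window: int
    n_out_window: int

    def for_length(self, length: int) -> pd.Series:
        """position -> count for one footprint length (zero-filled)."""
        sub = self.table[self.table["length"] == length]
        idx = pd.RangeIndex(self.window[0], self.window[1], name="position")
        return (
            sub.set_index("position")["count"].reindex(idx, fill_value=0).astype(int)
        )

    def total(self) -> pd.Series:
        """position -> count summed over lengths."""
        idx = pd.RangeIndex(self.window[0], self.window[1], name="position")
        s = self.table.groupby("position")["count"].sum()
        return s.reindex(idx, fill_value=0).astype(int)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def metagene_profile(
    reads: pd.DataFrame,
    genes: Iterable[GeneModel],
    anchor: str = "start",
    window: Tuple[int, int] = (-30, 33),
) -> MetageneProfile:
    """Aggregate 5'-end positions of reads on coding genes around an anchor.

    ``anchor="start"`` anchors at the first nt of the start codon,
    ``anchor="stop"`` at the first nt of the stop codon.  ``window`` is a
    half-open signed interval; reads whose 5' end falls outside it are
    tallied to ``n_out_window``.
    """
    if anchor not in ("start", "stop"):
        raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    w0, w1 = window
    if w0 >= w1:
        raise ValueError(f"window bounds must be ordered, got {window}")
    anchors = {
        g.gene_id: (g.cds_start if anchor == "start" else g.cds_end - 3)
        for g in genes
        if g.coding
    }
    sub = reads[reads["transcript_id"].isin(anchors)].copy()
    if len(sub) == 0:
        return MetageneProfile(
            anchor, window,
            pd.DataFrame(columns=["length", "position", "count"]), 0, 0,
        )
    a = sub["transcript_id"].map(anchors).to_numpy(np.int64)
    pos = sub["five_prime"].to_numpy(np.int64) - a
    inside = (pos >= w0) & (pos < w1)
    tab = (
        pd.DataFrame({"length": sub["length"].to_numpy()[inside], "position": pos[inside]})
        .groupby(["length", "position"])
        .size()
        .rename("count")
        .reset_index()
    )
    return MetageneProfile(anchor, window, tab, int(inside.sum()), int((~inside).sum()))


def calibrate_offsets(
    profile: MetageneProfile,
    lengths: Optional[Sequence[int]] = None,
    search_window: Tuple[int, int] = (-18, -6),
    min_reads: int = 500,
) -> OffsetTable:
    """Infer per-length A-site offsets from the start-codon 5'-end peak.

    For each length, the peak position ``p*`` is the argmax of the 5'-end
    histogram inside ``search_window`` (half-open); the offset is
    ``3 - p*`` (initiating ribosome: P-site on the start codon, A-site on
    codon 2).  Ties break toward the smaller ``|p*|``, then the smaller
    ``p*``.  Lengths with fewer than ``min_reads`` reads in the profile, or
    an all-zero search window, are omitted with a warning.
    """
    if profile.anchor != "start":
        raise ValueError("offset calibration requires a start-anchored profile")
    if profile.n_in_window + profile.n_out_window == 0 or len(profile.table) == 0:
        raise ValueError("empty metagene profile: nothing to calibrate")
    if lengths is None:
        lengths = sorted(profile.table["length"].unique())
    w0, w1 = search_window
    offsets = {}
    for length in lengths:
        hist = profile.for_length(int(length))
        n_total = int(hist.sum())
        if n_total < min_reads:
            logger.warning(
                "length %d: %d reads < min_reads=%d; omitted from calibration",
                length, n_total, min_reads,
            )
            continue
        window_hist = hist[(hist.index >= w0) & (hist.index < w1)]
        if len(window_hist) == 0 or window_hist.max() == 0:
            logger.warning(
                "length %d: no 5'-end signal in search window %s; omitted",
                length, (w0, w1),
            )
            continue
        peak = window_hist.max()
        candidates = sorted(
            window_hist.index[window_hist == peak], key=lambda p: (abs(p), p)
        )
        p_star = int(candidates[0])
        offsets[int(length)] = 3 - p_star
    return OffsetTable(offsets, provenance="calibrated")


@dataclass
class FrameReport:
    """A-site reading-frame fractions, per length and overall.

    ``per_length`` maps length -> (f0, f1, f2); ``overall`` is the pooled
    triple; ``n`` counts A-sites inside CDS bodies.  ``empty`` flags the
    degenerate no-reads case (fractions are then NaN).
    """

    per_length: Dict[int, Tuple[float, float, float]] = field(default_factory=dict)
    overall: Tuple[float, float, float] = (float("nan"),) * 3
    n: int = 0

    @property
    def empty(self) -> bool:
        return self.n == 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"length": k, "frame0": v[0], "frame1": v[1], "frame2": v[2]}
            for k, v in sorted(self.per_length.items())
        ]
        rows.append(
            {
                "length": "all",
                "frame0": self.overall[0],
                "frame1": self.overall[1],
                "frame2": self.overall[2],
            }
        )
        return pd.DataFrame(rows)


def frame_report(
    reads: pd.DataFrame,
    genes: Iterable[GeneModel],
    offsets: OffsetTable,
) -> FrameReport:
    """Tally A-site frames ``(five_prime + offset - cds_start) mod 3``.

    Only A-sites strictly inside the CDS of coding genes count; reads
    whose length has no offset are dropped (logged once).
    """
    info = {g.gene_id: (g.cds_start, g.cds_end) for g in genes if g.coding}
    sub = reads[reads["transcript_id"].isin(info)]
    known = sub["length"].isin(offsets.lengths)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("frame_report: dropped %d reads with unlisted lengths", n_dropped)
    sub = sub[known]
    if len(sub) == 0:
        return FrameReport()
    starts = sub["transcript_id"].map(lambda t: info[t][0]).to_numpy(np.int64)
    ends = sub["transcript_id"].map(lambda t: info[t][1]).to_numpy(np.int64)
    off = sub["length"].map(offsets.offsets).to_numpy(np.int64)
    site = sub["five_prime"].to_numpy(np.int64) + off
    in_cds = (site >= starts) & (site < ends)
    if not in_cds.any():
        return FrameReport()
    frame = (site[in_cds] - starts[in_cds]) % 3
    lengths = sub["length"].to_numpy(np.int64)[in_cds]
    per_length = {}
    for length in np.unique(lengths):
        f = frame[lengths == length]
        n = f.size
        per_length[int(length)] = tuple(float((f == k).sum()) / n for k in range(3))
    n_all = frame.size
    overall = tuple(float((frame == k).sum()) / n_all for k in range(3))
    return FrameReport(per_length, overall, int(n_all))


# ---------------------------------------------------------------------------
# plots (optional diagnostics; matplotlib imported lazily)


def plot_length_histogram(hist: Dict[int, int], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(list(hist.keys()), list(hist.values()), color="#4878b0")
    ax.set_xlabel("footprint length (nt)")
    ax.set_ylabel("reads")
    return ax


def plot_metagene(profile: MetageneProfile, length: Optional[int] = None, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = profile.total() if length is None else profile.for_length(length)
    ax.vlines(s.index, 0, s.to_numpy(), color="#b05454")
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"5' end position relative to {profile.anchor} codon (nt)")
    ax.set_ylabel("reads")
    return ax


def plot_frame_report(report: FrameReport, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(range(3), report.overall, color=["#4878b0", "#b0a648", "#b05454"])
    ax.set_xticks(range(3), [f"frame {k}" for k in range(3)])
    ax.set_ylabel("A-site fraction")
    return ax
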