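"""Sliding-window structure analytics over reactivity profiles.

Transcript-scale structure is summarized by windowed statistics: the
median reactivity over a moving 40–50 nt window (low median = structured,
high median = unstructured), and the per-position Pearson correlation
between two conditions over a ladder of window sizes (10–50 or 10–100 nt).
Regions whose windowed correlation sits more than ``t`` standard
deviations above (below) the track mean are called similar (dissimilar),
with t = 0.75 by default, and interval sets such as splice sites, protein
binding sites or conserved nucleotides are tested for enrichment in those
regions by re-placing the region intervals uniformly at random.

Windows are centered; positions whose window runs past the transcript end
are missing, so a track's support is constant across statistics.  All
intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowTrack",
    "RegionCalls",
    "sliding_median",
    "multiscale_correlation",
    "call_regions",
    "bootstrap_enrichment",
    "conservation_by_class",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
]


@dataclass
class WindowTrack:
    """A per-position windowed statistic (NaN = undefined)."""

    values: np.ndarray
    window_size: int
    statistic: str  # "median" | "pearson_r"

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class RegionCalls:
    """Similar/dissimilar intervals called from a correlation track."""

    similar: list[tuple[int, int]]
    dissimilar: list[tuple[int, int]]
    threshold_sd: float
    track_mean: float = float("nan")
    track_sd: float = float("nan")


def _odd_window(window_size: int) -> int:
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    if window_size % 2 == 0:
        return window_size + 1
    return window_size


def sliding_median(values, window_size: int = 41) -> WindowTrack:
    """Median reactivity over a centered moving window.

    Even window sizes round up to the next odd size.  The median ignores
    missing values but a position is undefined when fewer than half its
    window positions are usable, or when the window runs off either end.
    """
    v = np.asarray(values, dtype=float)
    w = _odd_window(window_size)
    if w > len(v):
        raise ValueError(f"window {w} larger than transcript ({len(v)} nt)")
    h = w // 2
    out = np.full(len(v), np.nan)
    for i in range(h, len(v) - h):
        win = v[i - h : i + h + 1]
        usable = win[~np.isnan(win)]
        if len(usable) >= 0.5 * w:
            out[i] = np.median(usable)
    return WindowTrack(out, w, "median")


def multiscale_correlation(values_a, values_b, window_sizes=(10, 20, 30, 40, 50)):
    """Windowed Pearson correlation between two profiles at several scales.

    For each window size (rounded up to odd, minimum 5) the track holds the
    correlation of pairwise-complete positions in the centered window;
    undefined with fewer than 5 complete pairs or when either window is
    constant.  Returns one :class:`WindowTrack` per requested scale.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    tracks = []
    for ws in window_sizes:
        if ws < 5:
            raise ValueError("window sizes must be >= 5")
        w = ws if ws % 2 == 1 else ws + 1
        if w > len(a):
            raise ValueError(f"window {w} larger than transcript")
        h = w // 2
        out = np.full(len(a), np.nan)
        for i in range(h, len(a) - h):
            x = a[i - h : i + h + 1]
            y = b[i - h : i + h + 1]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 5:
                continue
            xs, ys = x[ok], y[ok]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                continue
            out[i] = np.corrcoef(xs, ys)[0, 1]
        tracks.append(WindowTrack(out, w, "pearson_r"))
    return tracks


def _merge_adjacent(positions: np.ndarray) -> list[tuple[int, int]]:
    """Merge sorted positions into maximal half-open runs."""
    if len(positions) == 0:
        return []
    runs = []
    start = prev = int(positions[0])
    for p in positions[1:]:
        p = int(p)
        if p == prev + 1:
            prev = p
        else:
            runs.append((start, prev + 1))
            start = prev = p
    runs.append((start, prev + 1))
    return runs


def call_regions(track: WindowTrack, threshold_sd: float = 0.75) -> RegionCalls:
    """Call similar/dissimilar regions from a correlation track.

    Positions above ``mean + t*SD`` of the defined track values are
    similar, below ``mean - t*SD`` dissimilar; adjacent qualifying
    positions merge into half-open intervals.  A constant track (SD = 0)
    yields no calls.  Scale-free: affine rescaling of the track leaves the
    calls unchanged.
    """
    v = track.values if isinstance(track, WindowTrack) else np.asarray(track, float)
    defined = ~np.isnan(v)
    vals = v[defined]
    if len(np.unique(vals)) < 2:
        return RegionCalls([], [], threshold_sd,
                           float(vals.mean()) if len(vals) else float("nan"), 0.0)
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    hi = np.flatnonzero(defined & (v > mean + threshold_sd * sd))
    lo = np.flatnonzero(defined & (v < mean - threshold_sd * sd))
    return RegionCalls(_merge_adjacent(hi), _merge_adjacent(lo), threshold_sd, mean, sd)


# ---------------------------------------------------------------------------
# Enrichment against annotation tracks
# ---------------------------------------------------------------------------

def _feature_positions(features, transcript_length: int) -> np.ndarray:
    """Features may be point positions or half-open intervals."""
    mask = np.zeros(transcript_length, dtype=bool)
    for f in features:
        if np.isscalar(f):
            mask[int(f)] = True
        else:
            s, e = int(f[0]), int(f[1])
            mask[max(s, 0) : min(e, transcript_length)] = True
    return mask


def _overlap_count(region_list, feature_mask: np.ndarray) -> int:
    return int(sum(feature_mask[s:e].sum() for s, e in region_list))


def _random_placement(rng, lengths: list[int], transcript_length: int):
    """Uniform non-overlapping placement of intervals with given lengths."""
    k = len(lengths)
    free = transcript_length - sum(lengths)
    if free < 0:
        raise ValueError("regions longer than transcript")
    order = rng.permutation(k)
    ys = np.sort(rng.choice(free + k, size=k, replace=False))
    starts_sorted = []
    cum = 0
    for i, y in enumerate(ys):
        start = int(y) - i + cum
        starts_sorted.append(start)
        cum += lengths[order[i]]
    regions = [
        (s, s + lengths[order[i]]) for i, s in enumerate(starts_sorted)
    ]
    return regions


def bootstrap_enrichment(
    regions,
    features,
    transcript_length: int,
    n_boot: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
):
    """Test whether features fall inside ``regions`` more than chance.

    The observed statistic is the number of feature nucleotides inside the
    regions.  The null re-places the region intervals uniformly at random
    (preserving their count and lengths, without overlap) and recounts;
    the empirical p-value is ``(1 + #{null >= obs}) / (n_boot + 1)``
    (``less``/``two-sided`` available).  Returns
    ``(observed, null_counts, p)``.
    """
    regions = [(int(s), int(e)) for s, e in regions]
    for s, e in regions:
        if s < 0 or e > transcript_length or e <= s:
            raise ValueError(f"invalid region ({s}, {e})")
    if sum(e - s for s, e in regions) > transcript_length:
        raise ValueError("regions longer than transcript")
    feature_mask = _feature_positions(features, transcript_length)
    observed = _overlap_count(regions, feature_mask)
    lengths = [e - s for s, e in regions]
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot, dtype=int)
    for b in range(n_boot):
        placed = _random_placement(rng, lengths, transcript_length)
        null[b] = _overlap_count(placed, feature_mask)
    if alternative == "greater":
        p = (1 + int((null >= observed).sum())) / (n_boot + 1)
    elif alternative == "less":
        p = (1 + int((null <= observed).sum())) / (n_boot + 1)
    elif alternative == "two-sided":
        p_hi = (1 + int((null >= observed).sum())) / (n_boot + 1)
        p_lo = (1 + int((null <= observed).sum())) / (n_boot + 1)
        p = min(1.0, 2 * min(p_hi, p_lo))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return observed, null, float(p)


def conservation_by_class(scores, calls: RegionCalls):
    """Mean conservation score (e.g. PhyloP) per region class.

    Returns a dict with mean score over similar, dissimilar and remaining
    positions (NaN scores excluded; a class with no usable scores gets
    NaN) plus the similar-minus-dissimilar difference.
    """
    v = np.asarray(scores, dtype=float)
    n = len(v)
    in_class = {"similar": np.zeros(n, bool), "dissimilar": np.zeros(n, bool)}
    for name, ivals in (("similar", calls.similar), ("dissimilar", calls.dissimilar)):
        for s, e in ivals:
            in_class[name][s:e] = True
    in_class["neither"] = ~(in_class["similar"] | in_class["dissimilar"])
    out = {}
    for name, mask in in_class.items():
        usable = v[mask & ~np.isnan(v)]
        out[name] = float(usable.mean()) if len(usable) else float("nan")
    out["difference"] = out["similar"] - out["dissimilar"]
    return out


# ---------------------------------------------------------------------------
# Track I/O (bedGraph / BED, transcript coordinates)
# ---------------------------------------------------------------------------

def read_bedgraph(path, transcript_length: int, chrom: str | None = None) -> np.ndarray:
    """Expand a bedGraph into a dense per-position vector (NaN = no data)."""
    out = np.full(transcript_length, np.nan)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    for _, row in df.iterrows():
        out[int(row.start) : int(row.end)] = float(row.value)
    return out


def write_bedgraph(values, chrom: str, path) -> None:
    v = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        start = None
        for i in range(len(v) + 1):
            cur = v[i] if i < len(v) else np.nan
            if start is not None and (np.isnan(cur) or cur != v[start]):
                fh.write(f"{chrom}\t{start}\t{i}\t{v[start]:.6g}\n")
                start = None
            if start is None and i < len(v) and not np.isnan(cur):
                start = i


def read_bed(path, chrom: str | None = None) -> list[tuple[int, int]]:
    ivals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if chrom is not None and fields[0] != chrom:
                continue
            ivals.append((int(fields[1]), int(fields[2])))
    return ivals


def write_bed(intervals, chrom: str, path, names=None) -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals):
            name = names[i] if names else f"region{i + 1}"
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
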