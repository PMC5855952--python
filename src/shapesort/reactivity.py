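"""SHAPE-MaP reactivity profiles from aligned reads.

The estimator follows the standard MaP recipe: count per-position mutation
events and effective depth in the 1M7-treated and untreated (DMSO
background) channels, take the background-corrected rate difference

    raw_reactivity[i] = events_treated[i]/depth_treated[i]
                        - events_untreated[i]/depth_untreated[i]

wherever both depths pass ``min_depth``, and scale the profile by a single
positive multiplier from the 2%/8% box rule (exclude the top 2% of values,
divide by the mean of the next 8%).  Negative corrected values are real
(background fluctuation) and are scaled, not clipped, unless asked.

Profiles serialize to the community ``.map`` TSV (1-based position,
reactivity, stderr placeholder, nucleotide; missing = -999) plus an
extended TSV carrying rates, depths and the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MutationCounts",
    "ReactivityProfile",
    "count_mutations",
    "raw_reactivity",
    "normalize_profile",
    "box_multiplier",
    "write_profile",
    "read_profile",
]

DEFAULT_MIN_DEPTH = 1000
MISSING = -999.0

MASK_OK = "ok"
MASK_LOW_DEPTH = "low_depth"
MASK_VARIANT = "variant_site"


@dataclass
class MutationCounts:
    """Per-position mutation events and effective depth for one channel."""

    mutation_events: np.ndarray
    effective_depth: np.ndarray
    channel: str = "treated"

    def __post_init__(self):
        self.mutation_events = np.asarray(self.mutation_events, dtype=np.int64)
        self.effective_depth = np.asarray(self.effective_depth, dtype=np.int64)
        if self.mutation_events.shape != self.effective_depth.shape:
            raise ValueError("events/depth length mismatch")
        if np.any(self.mutation_events > self.effective_depth) or np.any(
            self.mutation_events < 0
        ):
            raise ValueError("0 <= mutation_events <= effective_depth violated")

    @property
    def rate(self) -> np.ndarray:
        """Mutation frequency; NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.effective_depth > 0,
                self.mutation_events / np.maximum(self.effective_depth, 1),
                np.nan,
            )


def count_mutations(
    reads, reference: str, min_base_quality: int = 0, collapse_adjacent: bool = False
) -> MutationCounts:
    """Count per-position mutation events and depth over a read set.

    ``effective_depth`` counts aligned, quality-passing base calls;
    ``mutation_events`` counts non-reference substitutions among them.
    With ``collapse_adjacent``, mismatches within 3 nt of each other on one
    read collapse into a single event at the 3'-most position, mimicking
    MaP multi-nucleotide mutation handling.  Order-independent.
    """
    ref = reference.upper().replace("U", "T")
    L = len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    events = np.zeros(L, dtype=np.int64)
    depth = np.zeros(L, dtype=np.int64)
    channel = "treated"
    for r in reads:
        if r.is_unmapped:
            continue
        if r.reference_end is not None and r.reference_end > L:
            raise ValueError("alignment extends past the reference")
        quals = r.query_qualities
        seq = r.query_sequence
        mismatch_pos = []
        for qpos, rpos in r.get_aligned_pairs(matches_only=True):
            if quals is not None and quals[qpos] < min_base_quality:
                continue
            depth[rpos] += 1
            if seq[qpos].upper().encode() != ref_arr[rpos]:
                mismatch_pos.append(rpos)
        if not mismatch_pos:
            continue
        if collapse_adjacent:
            mismatch_pos.sort()
            collapsed = []
            for p in mismatch_pos:
                if collapsed and p - collapsed[-1] <= 3:
                    collapsed[-1] = p  # merge into the 3'-most position
                else:
                    collapsed.append(p)
            mismatch_pos = collapsed
        for p in mismatch_pos:
            events[p] += 1
    return MutationCounts(events, depth, channel)


@dataclass
class ReactivityProfile:
    """Background-corrected (and optionally normalized) reactivity profile.

    ``raw_reactivity``/``normalized_reactivity`` use NaN for missing;
    ``mask`` records why a position is missing (low depth, variant site).
    """

    sequence: str
    raw_rate_treated: np.ndarray
    raw_rate_untreated: np.ndarray
    depth_treated: np.ndarray
    depth_untreated: np.ndarray
    raw_reactivity: np.ndarray
    normalized_reactivity: np.ndarray | None = None
    normalization_multiplier: float | None = None
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.where(
                np.isnan(self.raw_reactivity), MASK_LOW_DEPTH, MASK_OK
            ).astype(object)
        for arr in (
            self.raw_rate_treated,
            self.raw_rate_untreated,
            self.depth_treated,
            self.depth_untreated,
            self.raw_reactivity,
            self.mask,
        ):
            if len(arr) != len(self.sequence):
                raise ValueError("profile arrays must match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def reactivity(self) -> np.ndarray:
        """Normalized reactivity if available, else raw."""
        return (
            self.normalized_reactivity
            if self.normalized_reactivity is not None
            else self.raw_reactivity
        )

    def mask_position(self, position: int, reason: str = MASK_VARIANT) -> None:
        """Blank one position (e.g. the variant site, whose signal is the
        allele difference itself, not a SHAPE adduct)."""
        self.mask[position] = reason
        self.raw_reactivity[position] = np.nan
        if self.normalized_reactivity is not None:
            self.normalized_reactivity[position] = np.nan


def raw_reactivity(
    treated: MutationCounts,
    untreated: MutationCounts,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> np.ndarray:
    """Background-corrected mutation-rate difference per position.

    Missing (NaN) wherever either channel's depth is below ``min_depth``;
    negative values are retained at this stage.
    """
    if treated.effective_depth.shape != untreated.effective_depth.shape:
        raise ValueError("treated/untreated length mismatch")
    ok = (treated.effective_depth >= min_depth) & (untreated.effective_depth >= min_depth)
    out = np.full(len(treated.effective_depth), np.nan)
    out[ok] = treated.rate[ok] - untreated.rate[ok]
    return out


def make_profile_from_counts(
    sequence: str,
    treated: MutationCounts,
    untreated: MutationCounts,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> ReactivityProfile:
    """Bundle two channels of counts into a :class:`ReactivityProfile`."""
    raw = raw_reactivity(treated, untreated, min_depth)
    return ReactivityProfile(
        sequence=sequence,
        raw_rate_treated=treated.rate,
        raw_rate_untreated=untreated.rate,
        depth_treated=treated.effective_depth,
        depth_untreated=untreated.effective_depth,
        raw_reactivity=raw,
    )


def box_multiplier(values: np.ndarray) -> float:
    """The 2%/8% box normalization multiplier of a reactivity vector.

    Sort the non-missing values descending, exclude the top 2% (at least
    one value), and return 1 / mean of the next 8% (at least one value).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n < 20:
        raise ValueError(f"need >= 20 usable positions to normalize, got {n}")
    v = np.sort(v)[::-1]
    n_excl = max(1, int(n * 0.02))
    n_band = max(1, int(n * 0.08))
    band = v[n_excl : n_excl + n_band]
    mean = band.mean()
    if mean <= 0:
        raise ValueError("normalization band mean is not positive")
    return 1.0 / mean


def normalize_profile(
    profile: ReactivityProfile,
    method: str = "box2_8",
    reference_profile: np.ndarray | None = None,
    clip_negative: bool = False,
) -> ReactivityProfile:
    """Scale a raw profile to normalized SHAPE units (in place, returned).

    ``box2_8`` computes the 2%/8% multiplier from the profile itself;
    ``external_reference`` computes the same statistic from a supplied
    reference reactivity vector (the role played by a deeply probed
    full-length transcript) and applies it unchanged.  Missing positions
    stay missing; negatives are scaled (clipped to 0 only on request).
    """
    if method == "box2_8":
        mult = box_multiplier(profile.raw_reactivity)
    elif method == "external_reference":
        if reference_profile is None:
            raise ValueError("external_reference requires reference_profile")
        mult = box_multiplier(np.asarray(reference_profile, dtype=float))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    norm = profile.raw_reactivity * mult
    if clip_negative:
        norm = np.where(np.isnan(norm), norm, np.clip(norm, 0.0, None))
    profile.normalized_reactivity = norm
    profile.normalization_multiplier = float(mult)
    return profile


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_profile(profile: ReactivityProfile, path, extended_path=None) -> None:
    """Write a ``.map``-style TSV; optionally an extended TSV alongside.

    ``.map`` columns: 1-based position, reactivity (normalized when
    available), stderr placeholder 0, nucleotide; missing encoded as -999.
    The extended TSV is lossless (rates, depths, raw, normalized, mask).
    """
    if len(profile) == 0:
        raise ValueError("cannot write an empty profile")
    react = profile.reactivity
    out = np.where(np.isnan(react), MISSING, react)
    with open(path, "w") as fh:
        for i in range(len(profile)):
            fh.write(f"{i + 1}\t{out[i]:.6f}\t0\t{profile.sequence[i]}\n")
    if extended_path is not None:
        norm = (
            profile.normalized_reactivity
            if profile.normalized_reactivity is not None
            else np.full(len(profile), np.nan)
        )
        pd.DataFrame(
            {
                "position": np.arange(1, len(profile) + 1),
                "nucleotide": list(profile.sequence),
                "rate_treated": profile.raw_rate_treated,
                "rate_untreated": profile.raw_rate_untreated,
                "depth_treated": profile.depth_treated,
                "depth_untreated": profile.depth_untreated,
                "raw_reactivity": profile.raw_reactivity,
                "normalized_reactivity": norm,
                "mask": profile.mask,
            }
        ).to_csv(extended_path, sep="\t", index=False, float_format="%.8g")


def read_profile(path) -> ReactivityProfile:
    """Read a ``.map``-style TSV back into a (reactivity-only) profile."""
    positions, values, nucs = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            try:
                positions.append(int(fields[0]))
                values.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            nucs.append(fields[3])
    if not positions:
        raise ValueError(f"{path}: empty profile")
    n = len(positions)
    react = np.array(values)
    react[react == MISSING] = np.nan
    zeros = np.zeros(n)
    return ReactivityProfile(
        sequence="".join(nucs),
        raw_rate_treated=zeros.copy(),
        raw_rate_untreated=zeros.copy(),
        depth_treated=np.zeros(n, dtype=int),
        depth_untreated=np.zeros(n, dtype=int),
        raw_reactivity=react.copy(),
        normalized_reactivity=react.copy(),
    )
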