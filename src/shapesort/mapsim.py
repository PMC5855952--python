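"""Synthetic SHAPE-MaP read simulator with two-allele mixtures.

Mutational profiling (MaP) reads out chemical adducts on flexible (mostly
unpaired) nucleotides as mutations introduced during error-prone reverse
transcription.  This module emulates that chemistry end to end so every
downstream stage — allele sorting, reactivity estimation, riboSNitch
calling — can be tested against known ground truth:

* a ground-truth reactivity profile is drawn from separate paired/unpaired
  distributions given a dot-bracket structure;
* fragments are sampled along the transcript, assigned to the reference or
  alternate allele at a stated mixture fraction, and mutated per nucleotide
  with probability ``background_rate + mod_detection_scale * reactivity``
  (treated channel) or ``background_rate`` alone (untreated channel);
* reads are emitted as valid SAM; the true allele of every fragment goes to
  a sidecar TSV, never into the alignment the pipeline consumes.

Sequencing error is folded into ``background_rate`` (the analysis only ever
uses treated-minus-untreated differences), mutations are substitution-only,
and base qualities are a single constant Q.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import pysam

from .ensemble import pair_set

__all__ = [
    "GroundTruthProfile",
    "SimulationConfig",
    "VariantSpec",
    "make_profile",
    "simulate_reads",
    "perturb_replicate",
    "random_sequence",
    "write_sam",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class VariantSpec:
    """A single-nucleotide variant in transcript coordinates (0-based)."""

    position: int
    ref_base: str
    alt_base: str
    id: str = ""

    def __post_init__(self):
        ref = self.ref_base.upper().replace("U", "T")
        alt = self.alt_base.upper().replace("U", "T")
        object.__setattr__(self, "ref_base", ref)
        object.__setattr__(self, "alt_base", alt)
        if ref == alt:
            raise ValueError("ref_base and alt_base must differ")
        for b in (ref, alt):
            if b not in "ACGT":
                raise ValueError(f"invalid allele base {b!r}")
        if self.position < 0:
            raise ValueError("variant position must be >= 0")


@dataclass
class GroundTruthProfile:
    """Per-nucleotide ground-truth SHAPE reactivity with pairing state."""

    sequence: str
    reactivity: np.ndarray
    paired_mask: np.ndarray

    def __post_init__(self):
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.paired_mask = np.asarray(self.paired_mask, dtype=bool)
        n = len(self.sequence)
        if len(self.reactivity) != n or len(self.paired_mask) != n:
            raise ValueError("sequence/reactivity/paired_mask length mismatch")
        if np.any(self.reactivity < 0):
            raise ValueError("reactivities must be nonnegative")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def dna_sequence(self) -> str:
        """Sequence with U mapped to T, for read-level work."""
        return self.sequence.upper().replace("U", "T")


@dataclass
class SimulationConfig:
    """Knobs of the MaP simulator.

    ``depth`` counts fragments (read pairs), not per-position coverage.
    ``mod_detection_scale`` maps SHAPE reactivity to the per-nucleotide
    adduct-detection probability added on top of ``background_rate`` in the
    treated channel; defaults give a ~3% mutation rate at reactivity 1
    against a 0.2% background, typical of MaP libraries.
    ``allele_fraction_alt`` defaults to 0.75: the mutagenized (alt) template
    dominates the reaction and wild-type RNA makes up the remainder.
    """

    depth: int = 5000
    read_length: int = 50
    paired_end: bool = True
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 30.0
    mod_detection_scale: float = 0.03
    background_rate: float = 0.002
    allele_fraction_alt: float = 0.75
    replicate_noise_sd: float = 0.0
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        for name in ("background_rate", "allele_fraction_alt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")

    def to_file(self, path):
        """Write as a flat key=value file."""
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        kwargs = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        casts = {"depth": int, "read_length": int, "base_quality": int, "seed": int,
                 "paired_end": lambda s: s.strip().lower() in ("1", "true", "yes")}
        for lineno, raw in enumerate(open(path), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
            k, v = (x.strip() for x in line.split("=", 1))
            if k not in fields:
                raise ValueError(f"line {lineno}: unknown key {k!r}")
            kwargs[k] = casts.get(k, float)(v)
        return cls(**kwargs)


def random_sequence(length: int, seed: int = 0, rna: bool = False) -> str:
    """Uniform random nucleotide sequence (testing convenience)."""
    seq = "".join(np.random.default_rng(seed).choice(list("ACGT"), size=length))
    return seq.replace("T", "U") if rna else seq


def make_profile(
    sequence: str,
    structure: str,
    unpaired_dist_params: tuple[float, float] = (2.0, 0.6),
    paired_dist_params: tuple[float, float] = (0.6, 0.1),
    seed: int = 0,
) -> GroundTruthProfile:
    """Draw a ground-truth reactivity profile from a dot-bracket structure.

    Unpaired positions draw from Gamma(*unpaired_dist_params*) (shape,
    scale; default mean 1.2 SHAPE units) and paired positions from
    Gamma(*paired_dist_params*) (default mean 0.06), reproducing the
    low-median-reactivity signature of structured regions.  A scale of 0 is
    a point mass at 0.  Deterministic given ``seed``.
    """
    if len(sequence) != len(structure):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    pairs = pair_set(structure)  # raises on unbalanced input
    paired = np.zeros(len(sequence), dtype=bool)
    for i, j in pairs:
        paired[i] = paired[j] = True

    rng = np.random.default_rng(seed)
    react = np.empty(len(sequence))

    def _draw(params, size):
        shape, scale = params
        if scale == 0 or shape == 0:
            return np.zeros(size)
        return rng.gamma(shape, scale, size=size)

    react[~paired] = _draw(unpaired_dist_params, int((~paired).sum()))
    react[paired] = _draw(paired_dist_params, int(paired.sum()))
    return GroundTruthProfile(sequence=sequence, reactivity=react, paired_mask=paired)


def perturb_replicate(
    profile: GroundTruthProfile, replicate_noise_sd: float, seed: int = 0
) -> GroundTruthProfile:
    """Apply between-tube replicate noise to a ground-truth profile.

    Each reactivity is multiplied by an independent lognormal factor with
    log-scale SD ``replicate_noise_sd``; zero SD returns an identical copy.
    Multiplicative noise preserves zeros and nonnegativity.
    """
    if replicate_noise_sd < 0:
        raise ValueError("replicate_noise_sd must be >= 0")
    if replicate_noise_sd == 0:
        factors = np.ones(len(profile))
    else:
        rng = np.random.default_rng(seed)
        factors = rng.lognormal(mean=0.0, sigma=replicate_noise_sd, size=len(profile))
    return GroundTruthProfile(
        sequence=profile.sequence,
        reactivity=profile.reactivity * factors,
        paired_mask=profile.paired_mask.copy(),
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _sam_header(reference_name: str, length: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": reference_name, "LN": length}]}
    )


def simulate_reads(
    profile: GroundTruthProfile,
    variant: VariantSpec | None,
    config: SimulationConfig,
    channel: str = "treated",
    reference_name: str = "transcript",
):
    """Simulate a MaP sequencing run over one transcript.

    Each of ``config.depth`` fragments is placed uniformly on the reference,
    assigned to the alternate allele with probability
    ``config.allele_fraction_alt`` (when ``variant`` is given), and mutated
    per covered nucleotide: treated-channel probability is
    ``clamp(background_rate + mod_detection_scale * reactivity, 0, 1)``,
    untreated is ``background_rate``.  Mutations substitute a uniformly
    random non-template base.  Adducts live on the molecule, so overlapping
    mates of a pair share mutations.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    :class:`pysam.AlignedSegment` (pairs adjacent) and ``truth`` is a
    DataFrame with the true allele of every fragment.  Deterministic given
    ``config.seed`` and channel.
    """
    if channel not in ("treated", "untreated"):
        raise ValueError("channel must be 'treated' or 'untreated'")
    L = len(profile)
    cfg = config
    if cfg.read_length > L:
        raise ValueError("read/fragment longer than reference")

    seq_ref = np.frombuffer(profile.dna_sequence.encode(), dtype="S1").copy()
    seq_alt = seq_ref.copy()
    if variant is not None:
        if not 0 <= variant.position < L:
            raise ValueError("variant position outside reference")
        if seq_ref[variant.position] != variant.ref_base.encode():
            raise ValueError(
                f"reference base at {variant.position} is "
                f"{seq_ref[variant.position].decode()}, variant says {variant.ref_base}"
            )
        seq_alt[variant.position] = variant.alt_base.encode()

    if channel == "treated":
        p_mut = np.clip(
            cfg.background_rate + cfg.mod_detection_scale * profile.reactivity, 0.0, 1.0
        )
    else:
        p_mut = np.full(L, cfg.background_rate)

    rng = np.random.default_rng([cfg.seed, 0 if channel == "treated" else 1])
    n = cfg.depth
    if cfg.paired_end:
        frag = np.rint(
            rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, size=n)
        ).astype(int)
        frag = np.clip(frag, cfg.read_length, L)
    else:
        frag = np.full(n, min(cfg.read_length, L))
    starts = rng.integers(0, L - frag + 1)
    if variant is not None:
        is_alt = rng.random(n) < cfg.allele_fraction_alt
    else:
        is_alt = np.zeros(n, dtype=bool)

    header = _sam_header(reference_name, L)
    qual_arr = None
    reads: list[pysam.AlignedSegment] = []
    truth_rows = []
    pad = len(str(n))
    for i in range(n):
        s, f = int(starts[i]), int(frag[i])
        template = seq_alt if is_alt[i] else seq_ref
        frag_seq = template[s : s + f].copy()
        hits = np.nonzero(rng.random(f) < p_mut[s : s + f])[0]
        for h in hits:
            # substitute a uniformly random non-template base
            choices = _BASES[_BASES != frag_seq[h]]
            frag_seq[h] = choices[rng.integers(0, 3)]
        qname = f"sim{channel[0]}{i:0{pad}d}"
        truth_rows.append((qname, "alt" if is_alt[i] else "ref", s, f))

        rl = min(cfg.read_length, f)
        if qual_arr is None or len(qual_arr) != rl:
            qual_arr = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * rl)
        if cfg.paired_end:
            s2 = s + f - rl
            for mate_idx, (ms, flag) in enumerate(((s, 99), (s2, 147))):
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.flag = flag
                a.reference_id = 0
                a.reference_start = ms
                a.mapping_quality = 60
                a.cigarstring = f"{rl}M"
                a.query_sequence = frag_seq[ms - s : ms - s + rl].tobytes().decode()
                a.query_qualities = qual_arr
                a.next_reference_id = 0
                a.next_reference_start = s2 if mate_idx == 0 else s
                a.template_length = f if mate_idx == 0 else -f
                reads.append(a)
        else:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = 0
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.query_sequence = frag_seq[:rl].tobytes().decode()
            a.query_qualities = qual_arr
            reads.append(a)

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "true_allele", "fragment_start", "fragment_length"]
    )
    return reads, truth


def write_sam(reads, reference_name: str, reference_length: int, path) -> None:
    """Write simulated reads to a SAM file (v1.6 header, single reference)."""
    header = _sam_header(reference_name, reference_length)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            out.write(r)


def write_fasta(name: str, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the per-fragment allele truth sidecar TSV."""
    truth.to_csv(path, sep="\t", index=False)


def write_truth_profile(profile: GroundTruthProfile, path) -> None:
    """Write the ground-truth reactivity sidecar TSV (1-based positions)."""
    pd.DataFrame(
        {
            "position": np.arange(1, len(profile) + 1),
            "nucleotide": list(profile.sequence),
            "reactivity": profile.reactivity,
            "paired": profile.paired_mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
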