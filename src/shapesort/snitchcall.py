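"""riboSNitch calling from paired reactivity profiles, with evaluation.

A riboSNitch is a variant whose two alleles produce genuinely different
SHAPE reactivity profiles.  This module:

* summarizes a pair of aligned profiles into disruption features
  (correlations, the eSDC disruption statistic ``(1 - r) * sqrt(n)``,
  changed-position counts and runs, signed area before/after the variant),
  restricted to a window around the variant;
* classifies feature vectors as riboSNitch vs nonchanger, either by a
  monotone threshold rule on eSDC or by a random forest trained on
  synthetic changer/nonchanger comparisons;
* reproduces the two experimental-design evaluations: the traditional
  *between-replicate* comparison (profiles from independently handled
  tubes, hence replicate noise) versus the *within-sample* comparison
  (allele-sorted profiles from a single tube), scored by ROC/AUC and the
  false-call rate on nulls.  The within-sample design also supplies its
  own null via a ratiometric 75%/25% read split of one sample.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.ensemble import RandomForestClassifier

from .allele_sort import group_pairs
from .reactivity import ReactivityProfile, box_multiplier

__all__ = [
    "ComparisonFeatures",
    "SnitchCall",
    "ThresholdModel",
    "ForestModel",
    "compare_profiles",
    "classify",
    "train_on_synthetic",
    "save_model",
    "load_model",
    "ratiometric_split",
    "roc_auc",
    "evaluate_designs",
    "simulate_comparison",
    "DEFAULT_THRESHOLD",
]

DEFAULT_WINDOW_HALFWIDTH = 50   # nt each side of the variant
DEFAULT_CHANGE_THRESHOLD = 0.5  # normalized SHAPE units for a "changed" position
MIN_SHARED_POSITIONS = 10

# Default decision threshold on the [0, 1) disruption score, calibrated so
# that the synthetic within-sample null (ratiometric split of one tube,
# default simulator conditions) is called riboSNitch in <= 10% of cases.
# Recompute with calibrate_default_threshold().
DEFAULT_THRESHOLD = 0.079

FEATURE_NAMES = (
    "pearson_r",
    "spearman_rho",
    "esdc",
    "n_compared",
    "max_abs_delta",
    "n_changed",
    "longest_changed_run",
    "signed_area_before",
    "signed_area_after",
)


@dataclass(frozen=True)
class ComparisonFeatures:
    """Disruption features of one profile-vs-profile comparison."""

    pearson_r: float
    spearman_rho: float
    esdc: float
    n_compared: int
    max_abs_delta: float
    n_changed: int
    longest_changed_run: int
    signed_area_before: float
    signed_area_after: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


@dataclass(frozen=True)
class SnitchCall:
    variant_id: str
    score: float
    label: str  # "riboSNitch" | "nonchanger"
    window: tuple[int, int]


def _reactivity_vector(profile) -> np.ndarray:
    if isinstance(profile, ReactivityProfile):
        return np.asarray(profile.reactivity, dtype=float)
    return np.asarray(profile, dtype=float)


def _longest_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def compare_profiles(
    profile_ref,
    profile_alt,
    variant,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
) -> ComparisonFeatures:
    """Compute :class:`ComparisonFeatures` over a window around the variant.

    ``variant`` is a 0-based position or an object with ``.position``.
    The window is ``[pos - w, pos + w]`` clipped to the transcript, the
    variant position itself excluded; features use only positions
    non-missing in both profiles.  Raises if fewer than 10 shared
    positions remain.
    """
    a = _reactivity_vector(profile_ref)
    b = _reactivity_vector(profile_alt)
    if len(a) != len(b):
        raise ValueError("profiles must share a coordinate system")
    pos = getattr(variant, "position", variant)
    lo = max(0, pos - window_halfwidth)
    hi = min(len(a), pos + window_halfwidth + 1)
    idx = np.arange(lo, hi)
    idx = idx[idx != pos]
    shared = idx[~np.isnan(a[idx]) & ~np.isnan(b[idx])]
    n = len(shared)
    if n < MIN_SHARED_POSITIONS:
        raise ValueError(
            f"insufficient overlap: {n} shared positions (< {MIN_SHARED_POSITIONS})"
        )
    x, y = a[shared], b[shared]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # degenerate constant window: correlation undefined
        r = 1.0 if np.allclose(x, y) else 0.0
        rho = r
    else:
        r = float(pearsonr(x, y).statistic)
        rho = float(spearmanr(x, y).statistic)
    delta = y - x
    changed = np.abs(delta) >= change_threshold
    return ComparisonFeatures(
        pearson_r=r,
        spearman_rho=rho,
        esdc=(1.0 - r) * np.sqrt(n),
        n_compared=n,
        max_abs_delta=float(np.max(np.abs(delta))),
        n_changed=int(changed.sum()),
        longest_changed_run=_longest_run(changed),
        signed_area_before=float(delta[shared < pos].sum()),
        signed_area_after=float(delta[shared > pos].sum()),
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class ThresholdModel:
    """Monotone threshold rule on eSDC.

    The score ``1 - exp(-eSDC / esdc_scale)`` maps disruption to [0, 1)
    monotonically; the label is riboSNitch iff score >= threshold.
    """

    kind = "threshold"

    def __init__(self, threshold: float = DEFAULT_THRESHOLD, esdc_scale: float = 5.0):
        self.threshold = threshold
        self.esdc_scale = esdc_scale

    def score(self, features: ComparisonFeatures) -> float:
        return float(1.0 - np.exp(-max(features.esdc, 0.0) / self.esdc_scale))


class ForestModel:
    """Random-forest classifier over the full feature vector.

    Trained on synthetic changer/nonchanger comparisons; the score is the
    forest's riboSNitch class probability.
    """

    kind = "forest"

    def __init__(self, forest: RandomForestClassifier, threshold: float = 0.5):
        self.forest = forest
        self.threshold = threshold

    def score(self, features: ComparisonFeatures) -> float:
        proba = self.forest.predict_proba(features.to_array().reshape(1, -1))
        return float(proba[0, list(self.forest.classes_).index(1)])


def classify(features: ComparisonFeatures, model, variant_id: str = "",
             window: tuple[int, int] = (0, 0)) -> SnitchCall:
    """Label one comparison as riboSNitch or nonchanger.

    Identical profiles (zero disruption everywhere) are nonchangers under
    any model.
    """
    if model is None:
        raise ValueError("a model is required")
    if features.esdc == 0.0 and features.max_abs_delta == 0.0:
        return SnitchCall(variant_id, 0.0, "nonchanger", window)
    s = model.score(features)
    label = "riboSNitch" if s >= model.threshold else "nonchanger"
    return SnitchCall(variant_id, s, label, window)


def save_model(model, path) -> None:
    payload = {"format": 1, "kind": model.kind, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=4)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != 1:
        raise ValueError("unrecognized model file format")
    return payload["model"]


# ---------------------------------------------------------------------------
# Synthetic comparisons (training, calibration, nulls)
# ---------------------------------------------------------------------------

def _draw_truth(rng, n_positions: int) -> np.ndarray:
    """Ground-truth reactivity: a paired/unpaired gamma mixture."""
    paired = rng.random(n_positions) < 0.5
    out = np.where(
        paired,
        rng.gamma(0.6, 0.1, size=n_positions),
        rng.gamma(2.0, 0.6, size=n_positions),
    )
    return out


def _plant_effect(truth: np.ndarray, pos: int, effect: float, width: int) -> np.ndarray:
    """Add a local structural change: ``effect`` units over ``width`` nt
    starting 3 nt downstream of the variant (clipped to bounds)."""
    out = truth.copy()
    lo = min(pos + 3, len(out))
    hi = min(lo + width, len(out))
    out[lo:hi] = np.maximum(out[lo:hi] + effect, 0.0)
    return out


def _observe_counts(rng, truth, depth, background_rate, mod_detection_scale):
    """Count-level MaP observation: binomial mutation events at constant
    per-position depth, background-corrected to a raw reactivity vector."""
    p = np.clip(background_rate + mod_detection_scale * truth, 0.0, 1.0)
    et = rng.binomial(depth, p)
    eu = rng.binomial(depth, background_rate, size=truth.shape)
    return et / depth - eu / depth


def _normalized(raw: np.ndarray) -> np.ndarray:
    return raw * box_multiplier(raw)


def simulate_comparison(
    rng,
    effect: float = 0.0,
    noise_sd: float = 0.1,
    n_positions: int = 201,
    effect_width: int = 15,
    depth: int | None = None,
    background_rate: float = 0.002,
    mod_detection_scale: float = 0.03,
) -> ComparisonFeatures:
    """Simulate one profile-vs-profile comparison and return its features.

    Both profiles share one ground truth; each is observed through
    independent lognormal replicate noise (log-scale SD ``noise_sd``), and
    the alternate profile carries a planted ``effect`` (normalized units
    over ``effect_width`` nt) when nonzero.  With ``depth`` given, a
    count-level binomial observation layer is added on top.
    """
    pos = n_positions // 2
    truth = _draw_truth(rng, n_positions)
    truth_ref = truth
    truth_alt = _plant_effect(truth, pos, effect, effect_width) if effect else truth
    obs = []
    for t in (truth_ref, truth_alt):
        noisy = t * rng.lognormal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else t
        raw = (
            _observe_counts(rng, noisy, depth, background_rate, mod_detection_scale)
            if depth
            else noisy
        )
        obs.append(_normalized(raw))
    return compare_profiles(obs[0], obs[1], pos)


DEFAULT_EFFECT_GRID = (1.0, 1.5, 2.0)
DEFAULT_NOISE_GRID = (0.05, 0.1, 0.2, 0.3)


def train_on_synthetic(
    n_changers: int = 200,
    n_nonchangers: int = 200,
    effect_grid=DEFAULT_EFFECT_GRID,
    noise_grid=DEFAULT_NOISE_GRID,
    seed: int = 0,
    path=None,
) -> ForestModel:
    """Train a random forest on synthetic changer/nonchanger comparisons.

    Changers draw effect sizes from ``effect_grid`` and both classes draw
    replicate-noise SDs from ``noise_grid``.  Training is refused when the
    classes are indistinguishable (all effects zero) or when a class has
    fewer than 50 examples.  Reproducible given ``seed``; optionally
    persisted to ``path``.
    """
    if min(n_changers, n_nonchangers) < 50:
        raise ValueError("need >= 50 examples per class")
    effect_grid = tuple(effect_grid)
    noise_grid = tuple(noise_grid)
    if not any(e > 0 for e in effect_grid):
        raise ValueError("degenerate effect grid: classes are indistinguishable")
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, count in ((1, n_changers), (0, n_nonchangers)):
        for i in range(count):
            eff = effect_grid[i % len(effect_grid)] if label else 0.0
            noise = noise_grid[i % len(noise_grid)]
            feats = simulate_comparison(rng, effect=eff, noise_sd=noise)
            X.append(feats.to_array())
            y.append(label)
    forest = RandomForestClassifier(
        n_estimators=200, random_state=int(seed) % (2**31), n_jobs=1
    )
    forest.fit(np.array(X), np.array(y))
    model = ForestModel(forest)
    if path is not None:
        save_model(model, path)
    return model


def calibrate_default_threshold(
    n_null: int = 400,
    target_fpr: float = 0.10,
    depth: int = 3000,
    seed: int = 7_2026,
) -> float:
    """Threshold giving ``target_fpr`` false calls on the within-sample null.

    Simulates null comparisons the way the within-sample design produces
    them — one tube, count-level observation at the 75%/25% allele split
    depths, no replicate noise between the halves — scores them with the
    default :class:`ThresholdModel`, and returns the (1 - target_fpr)
    quantile of the null score distribution.
    """
    rng = np.random.default_rng(seed)
    model = ThresholdModel(threshold=1.0)  # scoring only
    scores = []
    for _ in range(n_null):
        truth = _draw_truth(rng, 201)
        raws = [
            _observe_counts(rng, truth, int(round(depth * f)), 0.002, 0.03)
            for f in (0.75, 0.25)
        ]
        feats = compare_profiles(_normalized(raws[0]), _normalized(raws[1]), 100)
        scores.append(model.score(feats))
    return float(np.quantile(scores, 1.0 - target_fpr))


# ---------------------------------------------------------------------------
# Ratiometric split and ROC
# ---------------------------------------------------------------------------

def ratiometric_split(reads, fractions=(0.75, 0.25), seed: int = 0):
    """Split a read set into disjoint subsets at the read-pair level.

    Subset sizes follow the fractions by largest-remainder rounding; the
    default 75%/25% mimics the allele mixture of the within-sample design
    so a sample can serve as its own null.  Raises when a subset would be
    empty or fewer than 20 pairs are available.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pairs = list(group_pairs(reads).values())
    n = len(pairs)
    if n < 20:
        raise ValueError(f"need >= 20 read pairs to split, got {n}")
    quotas = [f * n for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for i in np.argsort(remainders)[::-1][: n - sum(sizes)]:
        sizes[int(i)] += 1
    if any(s == 0 for s in sizes):
        raise ValueError("fractions would produce an empty subset")
    order = np.random.default_rng(seed).permutation(n)
    subsets, at = [], 0
    for s in sizes:
        subset = []
        for i in order[at : at + s]:
            subset.extend(pairs[int(i)])
        subsets.append(subset)
        at += s
    return tuple(subsets)


def roc_auc(scores, labels):
    """ROC curve and AUC with the Mann–Whitney tie convention.

    Thresholds sweep the distinct scores in descending order (tied scores
    share one threshold point); AUC is the trapezoid area, which equals the
    U statistic normalized by ``n1 * n0`` with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    fpr, tpr = [0.0], [0.0]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += l[j] == 1
            fp += l[j] == 0
            j += 1
        fpr.append(fp / n0)
        tpr.append(tp / n1)
        i = j
    fpr, tpr = np.array(fpr), np.array(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return {"fpr": fpr, "tpr": tpr}, auc


# ---------------------------------------------------------------------------
# Design comparison (between-replicate vs within-sample)
# ---------------------------------------------------------------------------

def evaluate_designs(
    effect_size: float,
    replicate_noise_sd: float,
    n_variants: int,
    depth: int,
    seed: int = 0,
    n_positions: int = 201,
    effect_width: int = 15,
    background_rate: float = 0.002,
    mod_detection_scale: float = 0.03,
    allele_fraction_alt: float = 0.75,
    model=None,
):
    """Score the same variant panel under both experimental designs.

    Half the variants are changers (planted ``effect_size``-unit block),
    half nonchangers.  The *between-replicate* design observes each allele
    in its own tube, so independent lognormal replicate noise (log-SD
    ``replicate_noise_sd``) separates the two profiles; each tube sequences
    at full ``depth`` per position.  The *within-sample* design observes
    both alleles in one tube — no between-tube noise, but the depth splits
    ``allele_fraction_alt : 1 - allele_fraction_alt`` between alleles.
    Observation is count-level binomial MaP sampling in both designs, and
    both are scored identically.

    Returns a dict per design with scores, truth labels, ROC points, AUC,
    and the nonchanger false-call fraction at the model threshold.
    """
    if n_variants < 4:
        raise ValueError("need >= 4 variants for a useful ROC")
    if depth <= 0 or n_positions <= 0:
        raise ValueError("depth and n_positions must be positive")
    model = model or ThresholdModel()
    rng = np.random.default_rng(seed)
    pos = n_positions // 2
    labels = np.zeros(n_variants, dtype=int)
    labels[: n_variants // 2] = 1
    results = {
        d: {"scores": [], "labels": labels}
        for d in ("between_replicate", "within_sample")
    }
    d_ref = int(round(depth * (1 - allele_fraction_alt)))
    d_alt = depth - d_ref
    for v in range(n_variants):
        truth_ref = _draw_truth(rng, n_positions)
        truth_alt = (
            _plant_effect(truth_ref, pos, effect_size, effect_width)
            if labels[v]
            else truth_ref
        )
        # between-replicate: one tube per allele, independent tube noise
        profs = []
        for t in (truth_ref, truth_alt):
            noisy = (
                t * rng.lognormal(0.0, replicate_noise_sd, size=t.shape)
                if replicate_noise_sd > 0
                else t
            )
            raw = _observe_counts(rng, noisy, depth, background_rate, mod_detection_scale)
            profs.append(_normalized(raw))
        feats = compare_profiles(profs[0], profs[1], pos)
        results["between_replicate"]["scores"].append(model.score(feats))
        # within-sample: shared tube, split depth, no between-allele noise
        tube = (
            rng.lognormal(0.0, replicate_noise_sd, size=n_positions)
            if replicate_noise_sd > 0
            else 1.0
        )
        profs = []
        for t, d in ((truth_ref, d_ref), (truth_alt, d_alt)):
            raw = _observe_counts(rng, t * tube, d, background_rate, mod_detection_scale)
            profs.append(_normalized(raw))
        feats = compare_profiles(profs[0], profs[1], pos)
        results["within_sample"]["scores"].append(model.score(feats))

    for d, res in results.items():
        res["scores"] = np.array(res["scores"])
        res["roc"], res["auc"] = roc_auc(res["scores"], labels)
        null_scores = res["scores"][labels == 0]
        res["fpr_at_threshold"] = float((null_scores >= model.threshold).mean())
    return results
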