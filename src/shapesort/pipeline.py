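"""Per-variant end-to-end orchestration and small utilities.

``run_variant`` chains the full within-sample workflow for one variant:
sort reads by allele, count mutations per allele and channel, build
background-corrected normalized reactivity profiles (masking the variant
site, whose apparent signal is the allele difference itself), compare the
profiles and call the variant.  ``run_batch`` drives it from files and
writes a report TSV plus a reproducibility manifest.  The qRT-PCR
relative-expression helper for mRNA stability assays also lives here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import pysam

from . import allele_sort, reactivity, snitchcall
from .mapsim import VariantSpec

__all__ = [
    "RunConfig",
    "CtRecord",
    "run_variant",
    "run_batch",
    "batch_report",
    "relative_expression",
    "read_fasta",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "variant_id", "position", "ref_base", "alt_base", "status", "reason",
    "n_ref_pairs", "n_alt_pairs", "n_other_pairs", "n_unassigned_pairs",
    "alt_fraction", "alt_fraction_lo", "alt_fraction_hi",
    "pearson_r", "spearman_rho", "esdc", "n_compared", "max_abs_delta",
    "n_changed", "longest_changed_run", "signed_area_before",
    "signed_area_after", "score", "call",
]


@dataclass
class RunConfig:
    """File paths and parameter overrides for a batch run."""

    reference_fasta: str
    variant_table: str
    treated_sam: str
    untreated_sam: str
    output_dir: str
    min_depth: int = reactivity.DEFAULT_MIN_DEPTH
    window_halfwidth: int = snitchcall.DEFAULT_WINDOW_HALFWIDTH
    min_base_quality: int = allele_sort.DEFAULT_MIN_BASE_QUALITY
    change_threshold: float = snitchcall.DEFAULT_CHANGE_THRESHOLD
    decision_threshold: float = snitchcall.DEFAULT_THRESHOLD
    model_path: str | None = None
    seed: int = 0


def read_fasta(path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (name, sequence)."""
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    raise ValueError(f"{path}: expected a single-record FASTA")
                name = line[1:].split()[0]
            else:
                chunks.append(line)
    if name is None or not chunks:
        raise ValueError(f"{path}: no FASTA record found")
    return name, "".join(chunks).upper()


def read_variant_table(path) -> list[VariantSpec]:
    """Read variants from a TSV with columns id, position (0-based), ref, alt."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "position", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: variant table needs columns {sorted(required)}")
    return [
        VariantSpec(int(r.position), str(r.ref), str(r.alt), str(r.id))
        for r in df.itertuples()
    ]


def run_variant(
    reference: str,
    variant: VariantSpec,
    treated_reads,
    untreated_reads,
    min_depth: int = reactivity.DEFAULT_MIN_DEPTH,
    window_halfwidth: int = snitchcall.DEFAULT_WINDOW_HALFWIDTH,
    min_base_quality: int = allele_sort.DEFAULT_MIN_BASE_QUALITY,
    change_threshold: float = snitchcall.DEFAULT_CHANGE_THRESHOLD,
    model=None,
):
    """Run the within-sample workflow for one variant.

    Returns ``(row, profiles, manifest)``: a report-row dict, the per-allele
    :class:`~shapesort.reactivity.ReactivityProfile` pair (or ``None`` when
    skipped), and a manifest of per-stage counts.  A variant that cannot be
    called is skipped with an explicit ``reason``, never silently dropped.
    """
    model = model or snitchcall.ThresholdModel()
    row = {c: np.nan for c in REPORT_COLUMNS}
    row.update(
        variant_id=variant.id or f"pos{variant.position}",
        position=variant.position,
        ref_base=variant.ref_base,
        alt_base=variant.alt_base,
    )
    manifest = {"variant_id": row["variant_id"], "stages": {}}

    sorted_channels = {}
    for channel, reads in (("treated", treated_reads), ("untreated", untreated_reads)):
        ref_reads, alt_reads, counts, _ = allele_sort.sort_reads(
            reads, variant, min_base_quality
        )
        sorted_channels[channel] = (ref_reads, alt_reads, counts)
        manifest["stages"][f"sort_{channel}"] = dict(counts)
    counts_t = sorted_channels["treated"][2]
    row.update(
        n_ref_pairs=counts_t["ref"], n_alt_pairs=counts_t["alt"],
        n_other_pairs=counts_t["other"], n_unassigned_pairs=counts_t["unassigned"],
    )
    if counts_t["ref"] + counts_t["alt"] == 0:
        row.update(status="skipped", reason="no informative reads")
        return row, None, manifest
    frac, (lo, hi) = allele_sort.estimate_allele_fraction(counts_t)
    row.update(alt_fraction=frac, alt_fraction_lo=lo, alt_fraction_hi=hi)

    profiles = {}
    for allele in ("ref", "alt"):
        idx = 0 if allele == "ref" else 1
        treated = reactivity.count_mutations(
            sorted_channels["treated"][idx], reference, min_base_quality
        )
        untreated = reactivity.count_mutations(
            sorted_channels["untreated"][idx], reference, min_base_quality
        )
        prof = reactivity.make_profile_from_counts(
            reference, treated, untreated, min_depth
        )
        prof.mask_position(variant.position)
        try:
            reactivity.normalize_profile(prof)
        except ValueError as exc:
            row.update(status="skipped", reason=f"{allele} allele: {exc}")
            return row, None, manifest
        profiles[allele] = prof
        manifest["stages"][f"profile_{allele}"] = {
            "usable_positions": int(np.sum(~np.isnan(prof.raw_reactivity))),
            "multiplier": prof.normalization_multiplier,
        }

    try:
        features = snitchcall.compare_profiles(
            profiles["ref"], profiles["alt"], variant,
            window_halfwidth, change_threshold,
        )
    except ValueError as exc:
        row.update(status="skipped", reason=str(exc))
        return row, None, manifest
    window = (
        max(0, variant.position - window_halfwidth),
        min(len(reference), variant.position + window_halfwidth + 1),
    )
    call = snitchcall.classify(features, model, row["variant_id"], window)
    for name in snitchcall.FEATURE_NAMES:
        row[name] = getattr(features, name)
    row.update(status="called", reason="", score=call.score, call=call.label)
    manifest["stages"]["compare"] = {"n_compared": features.n_compared,
                                     "window": list(window)}
    return row, (profiles["ref"], profiles["alt"]), manifest


def batch_report(rows) -> tuple[pd.DataFrame, dict]:
    """Tabulate per-variant rows and summarize the changer fraction.

    The summary fraction counts riboSNitches over all *called* variants;
    skipped variants are excluded from the denominator.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("batch_report requires at least one row")
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    n_snitch = int((df["call"] == "riboSNitch").sum())
    n_non = int((df["call"] == "nonchanger").sum())
    n_skipped = int((df["status"] == "skipped").sum())
    called = n_snitch + n_non
    summary = {
        "n_riboSNitch": n_snitch,
        "n_nonchanger": n_non,
        "n_skipped": n_skipped,
        "fraction_changed": n_snitch / called if called else float("nan"),
        "no_callable_variants": called == 0,
    }
    return df, summary


def run_batch(config: RunConfig):
    """File-level batch driver: report TSV, per-variant profiles, manifest.

    Deterministic: identical config and inputs reproduce byte-identical
    outputs (the manifest records parameters and per-stage counts, no
    timestamps).
    """
    from pathlib import Path

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_name, reference = read_fasta(config.reference_fasta)
    variants = read_variant_table(config.variant_table)
    with pysam.AlignmentFile(config.treated_sam, "r") as fh:
        treated = list(fh)
    with pysam.AlignmentFile(config.untreated_sam, "r") as fh:
        untreated = list(fh)
    model = (
        snitchcall.load_model(config.model_path)
        if config.model_path
        else snitchcall.ThresholdModel(threshold=config.decision_threshold)
    )
    rows, manifests = [], []
    for variant in variants:
        row, profiles, manifest = run_variant(
            reference, variant, treated, untreated,
            min_depth=config.min_depth,
            window_halfwidth=config.window_halfwidth,
            min_base_quality=config.min_base_quality,
            change_threshold=config.change_threshold,
            model=model,
        )
        if profiles is not None:
            for allele, prof in zip(("ref", "alt"), profiles):
                reactivity.write_profile(
                    prof, outdir / f"{row['variant_id']}.{allele}.map",
                    outdir / f"{row['variant_id']}.{allele}.profile.tsv",
                )
        logger.info("variant %s: %s", row["variant_id"], row["status"])
        rows.append(row)
        manifests.append(manifest)
    df, summary = batch_report(rows)
    df.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {
        "reference": ref_name,
        "parameters": {k: v for k, v in asdict(config).items()},
        "summary": summary,
        "variants": manifests,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return df, summary


# ---------------------------------------------------------------------------
# qRT-PCR relative expression (mRNA stability assay)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    """One qRT-PCR measurement: target (GFP) and control (GAPDH) cycles."""

    sample: str
    condition: str  # "dox" | "untreated"
    timepoint: str
    ct_target: float
    ct_control: float

    def __post_init__(self):
        if not (np.isfinite(self.ct_target) and np.isfinite(self.ct_control)):
            raise ValueError("cycle values must be finite")
        if self.ct_target <= 0 or self.ct_control <= 0:
            raise ValueError("cycle values must be positive")
        if self.condition not in ("dox", "untreated"):
            raise ValueError("condition must be 'dox' or 'untreated'")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_control


def relative_expression(records, literal_formula: bool = False) -> dict:
    """Doxycycline-induced relative expression per (sample, timepoint).

    Replicate ΔCT values (target − control) are averaged after dropping
    outliers more than 1 cycle from the replicate median (dropped
    replicates are logged).  The default interpretation is the exponential
    ΔΔCT convention ``2^(−ΔCT_dox) / 2^(−ΔCT_untreated)``;
    ``literal_formula`` instead computes ``(−ΔCT_dox)² / (−ΔCT_untreated)²``
    exactly as sometimes printed, which is retained for fidelity even
    though squaring a negative base is not a standard expression ratio.
    """
    records = list(records)
    if not records:
        raise ValueError("no Ct records")
    groups: dict[tuple[str, str, str], list[float]] = {}
    for r in records:
        groups.setdefault((r.sample, r.timepoint, r.condition), []).append(r.delta_ct)
    mean_dct = {}
    for key, dcts in groups.items():
        dcts = np.asarray(dcts, dtype=float)
        med = np.median(dcts)
        keep = np.abs(dcts - med) <= 1.0
        if not keep.all():
            logger.warning(
                "dropped %d outlier replicate(s) for %s", int((~keep).sum()), key
            )
        mean_dct[key] = float(dcts[keep].mean())
    out = {}
    pairs = {(s, t) for s, t, _ in mean_dct}
    for sample, timepoint in sorted(pairs):
        try:
            dct_dox = mean_dct[(sample, timepoint, "dox")]
            dct_unt = mean_dct[(sample, timepoint, "untreated")]
        except KeyError as exc:
            raise ValueError(
                f"unmatched dox/untreated pair for sample {sample!r}, "
                f"timepoint {timepoint!r}"
            ) from exc
        if literal_formula:
            if dct_unt == 0:
                raise ValueError("literal formula undefined for ΔCT_untreated = 0")
            value = (-dct_dox) ** 2 / (-dct_unt) ** 2
        else:
            value = 2.0 ** (-dct_dox) / 2.0 ** (-dct_unt)
        out[(sample, timepoint)] = value
    return out
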