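"""Synthetic amplicon genotypes and biased "observed" peak tables.

The generator reproduces the study conditions end to end: six AM-fungal
SSU amplicon genotypes (527–548 bp, GC 39.7–41.7%, mutually ≤97% identical,
uniquely sized TRFs per enzyme), the nine-template community design in
triplicate with triplicate technical fingerprints, and electropherogram
peak tables carrying the measurement artefacts documented for this assay:
linear TRF drift with Gaussian jitter, splitting of one TRF into 2–3
nearby peaks, pseudo-TRF peaks from under-digestion of mixed templates,
multiplicative (lognormal) area noise and a fluorescence detection floor.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .calibration import DEFAULT_DRIFT_FIT
from .community import (
    CommunityTemplate,
    PredictedProfile,
    build_predicted_profile,
    default_study_templates,
)
from .digest import GenotypeRecord, TRFTable, predict_trf_table
from .enzymes import DEFAULT_CHANNEL_RULE, DEFAULT_ENZYMES, RestrictionEnzyme

__all__ = [
    "BiasConfig",
    "StudyConfig",
    "StudyDataset",
    "generate_genotype_sequences",
    "simulate_observed_peak_table",
    "generate_study_dataset",
]

#: Fixed conversion from peak area to peak height used by the simulator;
#: only the ratio matters for threshold behaviour.
HEIGHT_PER_AREA = 0.5


@dataclass(frozen=True)
class BiasConfig:
    """Measurement-bias parameters for the peak-table simulator.

    Sizes: observed = predicted + drift_intercept + drift_slope·predicted
    + N(0, size_jitter_sd). With probability `split_prob` a TRF's area is
    split over 2–3 peaks spread within ±`split_spread` bp. `pseudo_rate` is
    the fraction of a genotype's area diverted to its pseudo-TRF lengths in
    a maximally rich template (scaled down for simpler templates).
    `area_noise_cv` is the lognormal coefficient of variation of peak
    areas; peaks whose height falls below `detection_floor` fluorescence
    units are not reported. Defaults are the calibrated regime fitted to
    the assay's published drift pairs.
    """

    drift_intercept: float = DEFAULT_DRIFT_FIT.intercept
    drift_slope: float = DEFAULT_DRIFT_FIT.slope
    size_jitter_sd: float = 1.0
    split_prob: float = 0.7
    split_spread: float = 4.0
    pseudo_rate: float = 0.03
    area_noise_cv: float = 0.10
    detection_floor: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.split_prob <= 1.0:
            raise ValueError("split_prob must lie in [0, 1]")
        if not 0.0 <= self.pseudo_rate < 1.0:
            raise ValueError("pseudo_rate must lie in [0, 1)")
        for name in ("size_jitter_sd", "split_spread", "area_noise_cv", "detection_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "BiasConfig":
        """Bias-free configuration: the simulated peak table round-trips to
        the predicted profile exactly."""
        return cls(
            drift_intercept=0.0,
            drift_slope=0.0,
            size_jitter_sd=0.0,
            split_prob=0.0,
            split_spread=0.0,
            pseudo_rate=0.0,
            area_noise_cv=0.0,
            detection_floor=0.0,
        )

    @classmethod
    def calibrated(cls, **overrides) -> "BiasConfig":
        """The drift-calibrated default regime, with optional overrides."""
        return replace(cls(), **overrides) if overrides else cls()


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences (edit distance over
    the longer length)."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence of exactly `length` bases with GC count round(gc·length)."""
    n_gc = int(round(gc * length))
    bases = np.concatenate(
        [
            rng.choice(["G", "C"], size=n_gc),
            rng.choice(["A", "T"], size=length - n_gc),
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


def generate_genotype_sequences(
    n: int = 6,
    length_range: tuple[int, int] = (527, 548),
    gc_range: tuple[float, float] = (0.397, 0.417),
    enzymes: Mapping[str, RestrictionEnzyme] | None = None,
    channel_rule: Mapping[str, str] | None = None,
    max_similarity: float = 0.97,
    min_trf_separation: float = 20.0,
    min_trf_bp: float = 120.0,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 5000,
) -> list[GenotypeRecord]:
    """Rejection-sample amplicon genotypes meeting the template-design criteria.

    Each accepted genotype: length and GC within the given ranges; complete
    TRF under every enzyme at least `min_trf_separation` bp from every other
    genotype's and at least `min_trf_bp` (so fragments stay inside the
    analysed >100 bp range under drift); at least two AluI sites (so
    under-digestion can produce pseudo-TRFs, as observed for this assay);
    all pairwise global-alignment identities ≤ `max_similarity`.
    Deterministic for a given seed.

    The default 20 bp TRF separation mirrors the spacing of the assay's
    reference genotypes and exceeds the drift-window width: TRFs closer
    than the drift range cannot be unambiguously matched to observed peaks
    once splitting and drift act, so "uniquely sized" must be read on the
    drift scale, not the 1-bp scale.
    """
    if not 2 <= n <= 12:
        raise ValueError("n must lie in 2..12")
    enzymes = dict(DEFAULT_ENZYMES if enzymes is None else enzymes)
    channel_rule = dict(DEFAULT_CHANNEL_RULE if channel_rule is None else channel_rule)
    rng = _rng(seed)
    accepted: list[GenotypeRecord] = []
    trfs: dict[str, list[float]] = {e: [] for e in enzymes}
    rejections: dict[str, int] = {}
    for attempt in range(max_attempts):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = float(rng.uniform(*gc_range))
        seq = _random_sequence(length, gc, rng)
        realised_gc = (seq.count("G") + seq.count("C")) / length
        if not gc_range[0] <= realised_gc <= gc_range[1]:
            rejections["gc"] = rejections.get("gc", 0) + 1
            continue
        rec = GenotypeRecord(id=f"G{len(accepted) + 1}", sequence=seq)
        table = predict_trf_table([rec], enzymes, channel_rule)
        ok = True
        new_trfs: dict[str, float] = {}
        for enz_name in enzymes:
            pred = table.lookup(rec.id, enz_name)
            trf = pred.complete_trf_bp
            if trf < min_trf_bp:
                rejections["short_trf"] = rejections.get("short_trf", 0) + 1
                ok = False
                break
            # >=2 AluI sites <=> >=2 pseudo lengths (k sites give k of them)
            if enz_name == "AluI" and len(pred.pseudo_trfs_bp) < 2:
                rejections["no_pseudo"] = rejections.get("no_pseudo", 0) + 1
                ok = False
                break
            if any(abs(trf - t) < min_trf_separation for t in trfs[enz_name]):
                rejections["trf_clash"] = rejections.get("trf_clash", 0) + 1
                ok = False
                break
            new_trfs[enz_name] = trf
        if not ok:
            continue
        if any(_identity(seq, other.sequence) > max_similarity for other in accepted):
            rejections["similarity"] = rejections.get("similarity", 0) + 1
            continue
        accepted.append(rec)
        for enz_name, trf in new_trfs.items():
            trfs[enz_name].append(trf)
        if len(accepted) == n:
            return accepted
    raise RuntimeError(
        f"could not generate {n} genotypes in {max_attempts} attempts "
        f"(got {len(accepted)}); rejections: {rejections}"
    )


def simulate_observed_peak_table(
    predicted: PredictedProfile,
    trf_table: TRFTable,
    bias: BiasConfig,
    total_area: float = 50000.0,
    sample_id: str = "sample",
    seed: int | np.random.Generator | None = None,
    richness_scale: float = 1.0,
) -> pd.DataFrame:
    """Simulate one channel's electropherogram peak table for a template.

    Each predicted TRF receives `total_area` × its relative abundance. A
    fraction ``pseudo_rate × richness_scale`` of a genotype's area is
    diverted equally across its pseudo-TRF lengths (under-digestion); the
    rest may split into 2–3 peaks; drift, jitter and lognormal area noise
    are applied; sub-floor peaks are dropped. Deterministic given a seed.
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    rng = _rng(bias.seed if seed is None else seed)
    preds = trf_table.for_enzyme(predicted.enzyme_name)
    rate = min(bias.pseudo_rate * richness_scale, 0.999)
    raw: list[tuple[float, float]] = []  # (true size, area)
    for trf_bp, abundance in sorted(predicted.abundance.items()):
        area_g = abundance * total_area
        pseudo_lengths = sorted(
            {pl for p in preds if p.complete_trf_bp == trf_bp for pl in p.pseudo_trfs_bp}
        )
        pseudo_area = area_g * rate if pseudo_lengths else 0.0
        for pl in pseudo_lengths:
            raw.append((pl, pseudo_area / len(pseudo_lengths)))
        remaining = area_g - pseudo_area
        if bias.split_prob > 0 and rng.random() < bias.split_prob:
            k = int(rng.integers(2, 4))
            offsets = rng.uniform(-bias.split_spread, bias.split_spread, size=k)
            weights = rng.dirichlet(np.ones(k))
            for off, w in zip(offsets, weights):
                raw.append((trf_bp + off, remaining * w))
        else:
            raw.append((trf_bp, remaining))
    rows = []
    sigma = float(np.sqrt(np.log1p(bias.area_noise_cv**2)))
    for size0, area in raw:
        if area <= 0:
            continue
        size = size0 + bias.drift_intercept + bias.drift_slope * size0
        if bias.size_jitter_sd > 0:
            size += rng.normal(0.0, bias.size_jitter_sd)
        if sigma > 0:
            area *= rng.lognormal(mean=-sigma**2 / 2, sigma=sigma)
        height = area * HEIGHT_PER_AREA
        if height < bias.detection_floor or size <= 0:
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "dye": predicted.dye,
                "size_bp": size,
                "height": height,
                "area": area,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "dye", "size_bp", "height", "area"])


@dataclass(frozen=True)
class StudyConfig:
    """Configuration for a full simulated study.

    Nine templates (equal / broken-stick at richness 4–6 and three
    near-equal pairs) × `n_replicates` independently pipetted mixes ×
    `n_tech_reps` technical fingerprints per enzyme channel — the study's
    9 × 3 × 3 design by default.
    """

    n_genotypes: int = 6
    length_range: tuple[int, int] = (527, 548)
    gc_range: tuple[float, float] = (0.397, 0.417)
    max_similarity: float = 0.97
    min_trf_separation: float = 20.0
    pair_deltas: tuple[float, ...] = (0.0, 0.025, 0.05)
    n_replicates: int = 3
    n_tech_reps: int = 3
    total_area: float = 50000.0
    pipetting_cv: float = 0.02
    bias: BiasConfig = field(default_factory=BiasConfig)
    seed: int = 0


@dataclass
class StudyDataset:
    """A complete simulated study: genotypes, design and peak tables.

    ``peak_tables`` maps enzyme name → one DataFrame holding every
    technical replicate's peaks for that channel; ``manifest`` has one row
    per sample (sample_id, template, replicate, tech_rep);
    ``predicted_profiles`` maps (template, replicate, enzyme) → the
    bias-free profile of that replicate's actual (pipetted) composition.
    """

    config: StudyConfig
    records: list[GenotypeRecord]
    trf_table: TRFTable
    templates: list[CommunityTemplate]
    replicate_templates: dict[tuple[str, int], CommunityTemplate]
    predicted_profiles: dict[tuple[str, int, str], PredictedProfile]
    peak_tables: dict[str, pd.DataFrame]
    manifest: pd.DataFrame

    @property
    def enzymes(self) -> list[str]:
        return sorted(self.peak_tables)

    def group_of(self) -> pd.Series:
        """sample_id → template-replicate group label."""
        g = self.manifest.set_index("sample_id").apply(
            lambda r: f"{r['template']}.r{r['replicate']}", axis=1
        )
        g.name = "group"
        return g


def _subseed(root: int, *parts) -> int:
    """Stable sub-seed (< 2**31) from the root seed and a key tuple."""
    key = "|".join(str(p) for p in parts).encode()
    return (root * 2654435761 + zlib.crc32(key)) % (2**31)


def generate_study_dataset(config: StudyConfig) -> StudyDataset:
    """Simulate the full study under `config` (deterministic in its seed)."""
    records = generate_genotype_sequences(
        n=config.n_genotypes,
        length_range=config.length_range,
        gc_range=config.gc_range,
        max_similarity=config.max_similarity,
        min_trf_separation=config.min_trf_separation,
        seed=np.random.default_rng(_subseed(config.seed, "genotypes")),
    )
    trf_table = predict_trf_table(records)
    templates = default_study_templates(
        [r.id for r in records], pair_deltas=config.pair_deltas
    )
    max_rich = max(t.richness for t in templates)
    replicate_templates: dict[tuple[str, int], CommunityTemplate] = {}
    predicted_profiles: dict[tuple[str, int, str], PredictedProfile] = {}
    peak_frames: dict[str, list[pd.DataFrame]] = {e: [] for e in DEFAULT_ENZYMES}
    manifest_rows = []
    for template in templates:
        for rep in range(1, config.n_replicates + 1):
            mix_rng = np.random.default_rng(_subseed(config.seed, "mix", template.name, rep))
            mixed = template.perturbed(
                config.pipetting_cv, mix_rng, f"{template.name}.r{rep}"
            )
            replicate_templates[(template.name, rep)] = mixed
            scale = (
                (template.richness - 1) / (max_rich - 1) if max_rich > 1 else 1.0
            )
            for enz_name in DEFAULT_ENZYMES:
                profile = build_predicted_profile(mixed, trf_table, enz_name)
                predicted_profiles[(template.name, rep, enz_name)] = profile
                for tech in range(1, config.n_tech_reps + 1):
                    sample_id = f"{template.name}.r{rep}.t{tech}"
                    peaks = simulate_observed_peak_table(
                        profile,
                        trf_table,
                        config.bias,
                        total_area=config.total_area,
                        sample_id=sample_id,
                        seed=np.random.default_rng(
                            _subseed(config.seed, template.name, rep, tech, enz_name)
                        ),
                        richness_scale=scale,
                    )
                    peak_frames[enz_name].append(peaks)
            for tech in range(1, config.n_tech_reps + 1):
                manifest_rows.append(
                    {
                        "sample_id": f"{template.name}.r{rep}.t{tech}",
                        "template": template.name,
                        "replicate": rep,
                        "tech_rep": tech,
                    }
                )
    peak_tables = {
        e: pd.concat(frames, ignore_index=True) for e, frames in peak_frames.items()
    }
    manifest = pd.DataFrame(manifest_rows)
    return StudyDataset(
        config=config,
        records=records,
        trf_table=trf_table,
        templates=templates,
        replicate_templates=replicate_templates,
        predicted_profiles=predicted_profiles,
        peak_tables=peak_tables,
        manifest=manifest,
    )
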