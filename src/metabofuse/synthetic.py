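"""Synthetic seasonal-harvest study generator.

Emulates a tropical-tree leaf metabolomics study sampled across the four
seasons with several independent harvests per season and replicate extracts
per harvest.  Two measurement blocks are produced for every sample:

* a 1D J-res projection spectrum (Lorentzian peaks on a ppm axis), and
* an aligned LC-MS feature table of per-sample peak areas.

Class-dependent metabolite patterns follow the phytochemistry the pipeline
is meant to detect: triterpene-like signals (aliphatic shifts 0.5-3.1 ppm,
apolar late-eluting m/z features) rise monotonically from spring to winter,
while C-glycosyl-flavone-like signals (aromatic shifts 6.5-8.0 ppm, earlier
glycoside m/z features) peak in spring.  All intensities carry
multiplicative log-normal noise; non-discriminant variables are
season-independent.  A ``GroundTruth`` sidecar records the planted
discriminant ids and their expected seasonal mean multipliers so downstream
selection can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ms import Feature, FeatureTable, Formula, adduct_mz, monoisotopic_mass
from .nmr import SpectrumProjection, bin_edges, bin_labels

__all__ = [
    "SEASONS",
    "StudyDesign",
    "SampleMetadata",
    "GroundTruth",
    "Study",
    "reference_library",
    "generate_projection",
    "generate_study",
    "write_study",
]

SEASONS = ["SPR", "SUM", "AUT", "WIN"]

QC_FEATURE_ID = "P9000"  # external standard (reserpine)
QC_RT = 11.38
QC_MZ = 609.2794


@dataclass
class StudyDesign:
    """Parameters of the simulated seasonal study.

    Defaults mirror the study conditions the pipeline targets: four seasons,
    three independent harvests per season with three replicate extracts
    each (36 samples), 0.0-9.0 ppm NMR projections, a 90-feature curated
    MS block, six planted discriminants per block, a four-fold seasonal
    effect and 20% intensity noise.
    """

    n_seasons: int = 4
    harvests_per_season: int = 3
    replicates_per_harvest: int = 3
    n_nmr_points: int = 2048
    ppm_range: tuple[float, float] = (0.0, 9.0)
    n_ms_features: int = 90
    n_discriminant_features: int = 6
    effect_size: float = 4.0
    noise_cv: float = 0.2
    seed: int = 0
    n_blanks: int = 2
    n_contaminants: int = 3

    def __post_init__(self) -> None:
        for name in (
            "n_seasons",
            "harvests_per_season",
            "replicates_per_harvest",
            "n_nmr_points",
            "n_ms_features",
            "n_discriminant_features",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"design field {name!r} must be a positive integer, got {v!r}")
        if not (2 <= self.n_seasons <= len(SEASONS)):
            raise ValueError(f"design field 'n_seasons' must be in [2, {len(SEASONS)}]")
        if self.effect_size < 1:
            raise ValueError(f"design field 'effect_size' must be >= 1, got {self.effect_size}")
        if self.noise_cv < 0:
            raise ValueError(f"design field 'noise_cv' must be >= 0, got {self.noise_cv}")
        lo, hi = self.ppm_range
        if not hi > lo:
            raise ValueError(f"design field 'ppm_range' must satisfy lower < upper, got {self.ppm_range}")
        if self.n_blanks < 0 or self.n_contaminants < 0:
            raise ValueError("design fields 'n_blanks'/'n_contaminants' must be >= 0")
        if self.n_discriminant_features > self.n_ms_features:
            raise ValueError(
                "design field 'n_discriminant_features' cannot exceed 'n_ms_features'"
            )
        if self.n_discriminant_features > 13:
            raise ValueError(
                "design field 'n_discriminant_features' is limited to 13 per block "
                "(distinct chemical-shift slots available)"
            )

    @property
    def seasons(self) -> list[str]:
        return SEASONS[: self.n_seasons]

    @property
    def n_samples(self) -> int:
        return self.n_seasons * self.harvests_per_season * self.replicates_per_harvest


@dataclass
class SampleMetadata:
    sample_id: str
    season: str
    harvest: int
    replicate: int
    temperature: float
    radiation: float
    humidity: float
    rainfall: float


@dataclass
class GroundTruth:
    """Planted discriminant ids and their expected seasonal mean multipliers."""

    discriminant_ids: dict[str, list[str]]  # block -> ids
    season_profile: dict[str, dict[str, float]]  # id -> season -> multiplier

    def all_ids(self) -> list[str]:
        return [i for ids in self.discriminant_ids.values() for i in ids]


@dataclass
class Study:
    design: StudyDesign
    projections: list[SpectrumProjection]
    features: FeatureTable
    metadata: list[SampleMetadata]
    truth: GroundTruth

    @property
    def labels(self) -> list[str]:
        return [m.season for m in self.metadata]

    @property
    def blank_ids(self) -> list[str]:
        return [s for s in self.features.sample_ids if s.startswith("BLANK")]


# ---------------------------------------------------------------------------
# reference compounds for dereplication and MS-feature flavor

_LIBRARY_ROWS = [
    # name, formula, taxon, class, polarity, rt (min)
    ("Ursolic acid", "C30H48O3", "Terminalia;Combretaceae", "triterpene", "positive", 24.0),
    ("Hydroxyursolic acid", "C30H48O4", "Terminalia;Combretaceae", "triterpene", "positive", 22.9),
    ("Asiatic acid", "C30H48O5", "Terminalia;Combretaceae", "triterpene", "positive", 17.4),
    ("Tetrahydroxyolean-12-en-28-oic acid", "C30H48O6", "Terminalia;Combretaceae", "triterpene", "negative", 15.7),
    ("Trihydroxyursadien-28-oic acid", "C30H46O5", "Terminalia;Combretaceae", "triterpene", "negative", 16.5),
    ("Isovitexin", "C21H20O10", "Terminalia;Combretaceae", "flavone", "positive", 7.7),
    ("Isoorientin", "C21H20O11", "Terminalia;Combretaceae", "flavone", "positive", 6.7),
    ("Galloyl-C-hexosyl apigenin", "C28H24O14", "Terminalia;Combretaceae", "flavone", "positive", 8.4),
    ("Galloyl-C-hexosyl luteolin", "C28H24O15", "Terminalia;Combretaceae", "flavone", "positive", 8.1),
    ("Punicalagin", "C48H28O30", "Terminalia;Combretaceae", "tannin", "negative", 3.5),
    ("Corilagin", "C27H22O18", "Terminalia;Combretaceae", "tannin", "negative", 4.1),
    ("Ellagic acid", "C14H6O8", "Terminalia;Combretaceae", "phenolic", "negative", 6.2),
    ("Gallic acid", "C7H6O5", "Terminalia;Combretaceae", "phenolic", "negative", 1.5),
    ("Quinine", "C20H24N2O2", "Cinchona;Rubiaceae", "alkaloid", "positive", 5.6),
    ("Caffeine", "C8H10N4O2", "Coffea;Rubiaceae", "alkaloid", "positive", 4.2),
]


def reference_library() -> pd.DataFrame:
    """Small built-in compound library (name, formula, neutral_mass, taxon)."""
    rows = []
    for name, formula, taxon, cls, polarity, rt in _LIBRARY_ROWS:
        rows.append(
            {
                "name": name,
                "formula": formula,
                "neutral_mass": monoisotopic_mass(formula),
                "taxon": taxon,
                "compound_class": cls,
                "polarity": polarity,
                "rt_min": rt,
            }
        )
    return pd.DataFrame(rows)


# chemical-shift pools for planted NMR discriminants (ppm)
_TRITERPENE_SHIFTS = [0.55, 0.95, 1.27, 1.91, 2.19, 2.55, 3.03]
_FLAVONE_SHIFTS = [6.55, 6.67, 6.79, 7.31, 7.55, 7.95]


def generate_projection(
    peaks: Sequence[tuple[float, float, float]],
    axis: np.ndarray,
    noise_scale: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
) -> SpectrumProjection:
    """Synthesize a projection as a sum of Lorentzian lines plus baseline.

    ``peaks`` is a list of (ppm center, height, half-width-at-half-maximum);
    the baseline noise is non-negative (half-normal with scale
    ``noise_scale``) so intensities stay physical.
    """
    axis = np.asarray(axis, dtype=float)
    lo, hi = float(axis.min()), float(axis.max())
    intensity = np.zeros_like(axis)
    for center, height, width in peaks:
        if width <= 0:
            raise ValueError(f"peak width must be positive, got {width}")
        if not (lo <= center <= hi):
            raise ValueError(f"peak center {center} ppm outside axis range [{lo}, {hi}]")
        intensity += height * width**2 / (width**2 + (axis - center) ** 2)
    if noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        intensity += np.abs(rng.normal(0.0, noise_scale, size=axis.size))
    return SpectrumProjection(sample_id, axis, intensity)


def _season_multiplier(effect: float, rank: float, n_seasons: int, direction: str) -> float:
    """Monotone multiplicative seasonal trend between the extreme seasons."""
    frac = rank / (n_seasons - 1)
    if direction == "SPR":  # maximal in spring, minimal in winter
        frac = 1.0 - frac
    return float(effect**frac)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv**2)))


def generate_study(design: StudyDesign) -> Study:
    """Generate the full synthetic study (bit-reproducible given the seed).

    Randomness is split into a structure stream (where peaks and features
    live) and per-sample streams, all deterministically derived from
    ``design.seed``.
    """
    seasons = design.seasons
    struct_rng = np.random.default_rng([design.seed, 0])
    sigma = _lognormal_sigma(design.noise_cv)
    lo, hi = design.ppm_range
    axis = np.linspace(lo, hi, design.n_nmr_points)
    width = 0.04
    edges = bin_edges(lo, hi, width)
    labels = bin_labels(edges)

    def snap_to_bin_center(ppm: float) -> float:
        b = min(int((ppm - lo) / width), len(edges) - 2)
        return float(edges[b] + width / 2)

    # --- planted NMR discriminants: half triterpene-like (winter max),
    # half flavone-like (spring max)
    n_disc = design.n_discriminant_features
    n_tri = (n_disc + 1) // 2
    n_fla = n_disc - n_tri
    tri_shifts = [_TRITERPENE_SHIFTS[i % len(_TRITERPENE_SHIFTS)] for i in range(n_tri)]
    fla_shifts = [_FLAVONE_SHIFTS[i % len(_FLAVONE_SHIFTS)] for i in range(n_fla)]
    planted_nmr = []
    for shift, direction in [(s, "WIN") for s in tri_shifts] + [(s, "SPR") for s in fla_shifts]:
        center = snap_to_bin_center(shift)
        b = min(int((center - lo) / width), len(labels) - 1)
        planted_nmr.append(
            {
                "label": labels[b],
                "center": center,
                "direction": direction,
                "height": float(struct_rng.lognormal(np.log(5.0), 0.2)),
                "width": float(struct_rng.uniform(0.005, 0.008)),
            }
        )

    # --- season-independent background peaks, kept away from planted bins
    n_background = 25
    background = []
    planted_centers = np.array([p["center"] for p in planted_nmr])
    while len(background) < n_background:
        c = float(struct_rng.uniform(lo + 0.3, hi - 0.3))
        if np.min(np.abs(planted_centers - c)) < 2.5 * width:
            continue
        background.append(
            {
                "center": c,
                "height": float(struct_rng.lognormal(np.log(2.0), 0.6)),
                "width": float(struct_rng.uniform(0.005, 0.009)),
            }
        )

    # --- MS feature skeleton
    lib = reference_library()
    in_taxon = lib[lib.taxon.str.contains("Terminalia")]
    tri_lib = in_taxon[in_taxon.compound_class == "triterpene"].to_dict("records")
    fla_lib = in_taxon[in_taxon.compound_class == "flavone"].to_dict("records")
    other_lib = in_taxon[~in_taxon.compound_class.isin(["triterpene", "flavone"])].to_dict("records")

    ms_rows = []  # feature_id, mz, rt, polarity, direction|None, base area

    def adduct_for(pol: str) -> str:
        return "[M+H]+" if pol == "positive" else "[M-H]-"

    def planted_mz(entry) -> float:
        theo = adduct_mz(entry["neutral_mass"], adduct_for(entry["polarity"]))
        return theo * (1.0 + struct_rng.uniform(-1.5, 1.5) * 1e-6)

    counter = {"P": 0, "N": 0}

    def new_id(pol: str) -> str:
        pref = "P" if pol == "positive" else "N"
        counter[pref] += 1
        return f"{pref}{counter[pref]}"

    n_ms_tri = (n_disc + 1) // 2
    n_ms_fla = n_disc - n_ms_tri
    for i in range(n_ms_tri):
        e = tri_lib[i % len(tri_lib)]
        ms_rows.append(
            {
                "feature_id": new_id(e["polarity"]),
                "mz": planted_mz(e),
                "rt": e["rt_min"] + float(struct_rng.normal(0, 0.05)),
                "polarity": e["polarity"],
                "direction": "WIN",
                "base": float(struct_rng.lognormal(np.log(2e6), 0.3)),
            }
        )
    for i in range(n_ms_fla):
        e = fla_lib[i % len(fla_lib)]
        ms_rows.append(
            {
                "feature_id": new_id(e["polarity"]),
                "mz": planted_mz(e),
                "rt": e["rt_min"] + float(struct_rng.normal(0, 0.05)),
                "polarity": e["polarity"],
                "direction": "SPR",
                "base": float(struct_rng.lognormal(np.log(2e6), 0.3)),
            }
        )
    # non-discriminant library compounds (constitutive chemistry)
    for e in other_lib:
        if len(ms_rows) >= design.n_ms_features:
            break
        ms_rows.append(
            {
                "feature_id": new_id(e["polarity"]),
                "mz": planted_mz(e),
                "rt": e["rt_min"] + float(struct_rng.normal(0, 0.05)),
                "polarity": e["polarity"],
                "direction": None,
                "base": float(struct_rng.lognormal(np.log(1e6), 0.6)),
            }
        )
    # anonymous background features
    while len(ms_rows) < design.n_ms_features:
        pol = "positive" if struct_rng.random() < 0.5 else "negative"
        ms_rows.append(
            {
                "feature_id": new_id(pol),
                "mz": float(np.exp(struct_rng.uniform(np.log(150.0), np.log(1500.0)))),
                "rt": float(struct_rng.uniform(1.0, 30.0)),
                "polarity": pol,
                "direction": None,
                "base": float(struct_rng.lognormal(np.log(5e5), 1.0)),
            }
        )

    # --- samples
    sample_ids, metadata = [], []
    climate_base = {
        "SPR": (23.0, 19.0, 74.0, 160.0),
        "SUM": (28.0, 23.0, 80.0, 230.0),
        "AUT": (25.0, 17.0, 77.0, 120.0),
        "WIN": (19.0, 14.0, 70.0, 45.0),
    }
    for season in seasons:
        for h in range(1, design.harvests_per_season + 1):
            harvest_rng = np.random.default_rng([design.seed, 2, seasons.index(season), h])
            t, r, hu, ra = climate_base[season]
            climate = (
                t + harvest_rng.normal(0, 1.5),
                r + harvest_rng.normal(0, 1.5),
                hu + harvest_rng.normal(0, 3.0),
                max(0.0, ra + harvest_rng.normal(0, 20.0)),
            )
            for rep in range(1, design.replicates_per_harvest + 1):
                sid = f"{season}_h{h}_r{rep}"
                sample_ids.append(sid)
                metadata.append(SampleMetadata(sid, season, h, rep, *[float(c) for c in climate]))

    projections = []
    areas: dict[str, dict[str, float]] = {row["feature_id"]: {} for row in ms_rows}
    baseline_scale = 0.02
    for i, (sid, meta) in enumerate(zip(sample_ids, metadata)):
        rng = np.random.default_rng([design.seed, 1, i])
        g = float(rng.lognormal(0.0, _lognormal_sigma(0.05)))  # sample dilution factor
        srank = seasons.index(meta.season)
        peaks = []
        for p in planted_nmr:
            mult = _season_multiplier(design.effect_size, srank, design.n_seasons, p["direction"])
            h = p["height"] * mult * g * float(rng.lognormal(0.0, sigma))
            peaks.append((p["center"], h, p["width"]))
        for b in background:
            h = b["height"] * g * float(rng.lognormal(0.0, sigma))
            peaks.append((b["center"], h, b["width"]))
        projections.append(
            generate_projection(peaks, axis, noise_scale=baseline_scale, rng=rng, sample_id=sid)
        )
        for row in ms_rows:
            mult = (
                _season_multiplier(design.effect_size, srank, design.n_seasons, row["direction"])
                if row["direction"]
                else 1.0
            )
            areas[row["feature_id"]][sid] = row["base"] * mult * g * float(rng.lognormal(0.0, sigma))

    # --- QC standard, contaminants and solvent blanks
    blank_ids = [f"BLANK{i + 1}" for i in range(design.n_blanks)]
    qc_rng = np.random.default_rng([design.seed, 3])
    all_ids = sample_ids + blank_ids
    features = []
    for row in ms_rows:
        a = areas[row["feature_id"]]
        for b in blank_ids:
            a[b] = 0.0
        features.append(Feature(row["feature_id"], row["mz"], row["rt"], row["polarity"], a))
    qc_areas = {s: float(qc_rng.lognormal(np.log(1e6), 0.05)) for s in sample_ids}
    qc_areas.update({b: 0.0 for b in blank_ids})
    features.append(Feature(QC_FEATURE_ID, QC_MZ, QC_RT, "positive", qc_areas))
    for j in range(design.n_contaminants):
        a = {s: float(qc_rng.lognormal(np.log(3e5), 0.4)) for s in all_ids}
        features.append(
            Feature(
                f"P{9100 + j}",
                float(np.exp(qc_rng.uniform(np.log(200.0), np.log(600.0)))),
                float(qc_rng.uniform(1.0, 30.0)),
                "positive",
                a,
            )
        )
    table = FeatureTable(features=features, sample_ids=all_ids)

    # --- ground truth
    profile: dict[str, dict[str, float]] = {}
    nmr_ids = [p["label"] for p in planted_nmr]
    ms_ids = [row["feature_id"] for row in ms_rows if row["direction"]]
    for p in planted_nmr:
        profile[p["label"]] = {
            s: _season_multiplier(design.effect_size, k, design.n_seasons, p["direction"])
            for k, s in enumerate(seasons)
        }
    for row in ms_rows:
        if row["direction"]:
            profile[row["feature_id"]] = {
                s: _season_multiplier(design.effect_size, k, design.n_seasons, row["direction"])
                for k, s in enumerate(seasons)
            }
    truth = GroundTruth(
        discriminant_ids={"NMR": nmr_ids, "MS": ms_ids}, season_profile=profile
    )
    return Study(design, projections, table, metadata, truth)


# ---------------------------------------------------------------------------
# on-disk form (the same delimited formats the real-data path reads)


def write_study(study: Study, outdir: str | Path) -> dict[str, Path]:
    """Write the study in the pipeline's input formats plus the truth sidecar."""
    outdir = Path(outdir)
    nmr_dir = outdir / "nmr"
    nmr_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for spec in study.projections:
        p = nmr_dir / f"{spec.sample_id}.tsv"
        np.savetxt(p, np.column_stack([spec.ppm, spec.intensity]), delimiter="\t", fmt="%.8g")
        manifest_rows.append((spec.sample_id, f"nmr/{spec.sample_id}.tsv"))
    manifest = outdir / "nmr_manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", header=False, index=False)

    from .ms import write_feature_table

    ft_path = outdir / "ms_features.csv"
    write_feature_table(study.features, ft_path)

    meta_path = outdir / "metadata.csv"
    pd.DataFrame([vars(m) for m in study.metadata]).to_csv(meta_path, index=False)

    lib_path = outdir / "library.csv"
    reference_library().to_csv(lib_path, index=False)

    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "discriminant_ids": study.truth.discriminant_ids,
                "season_profile": study.truth.season_profile,
            },
            indent=2,
        )
    )
    return {
        "manifest": manifest,
        "features": ft_path,
        "metadata": meta_path,
        "library": lib_path,
        "truth": truth_path,
    }
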