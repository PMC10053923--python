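"""LC-MS feature-table curation, accurate-mass arithmetic and dereplication.

The pipeline consumes an aligned feature table as exported after MZmine-style
processing (feature id with N/P polarity prefix, m/z, retention time,
polarity, per-sample peak areas).  This module curates that table (solvent
blank subtraction, external-standard QC), computes monoisotopic masses,
adduct m/z values and ppm errors, predicts molecular formulas under elemental
and heuristic constraints, and dereplicates features against a compound
library by accurate mass.  Matches made on accurate mass alone are annotated
at confidence Level 3 (putatively characterized compound class).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "Formula",
    "FormulaConstraints",
    "Feature",
    "FeatureTable",
    "Annotation",
    "QcReport",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "predict_formula",
    "remove_blank_features",
    "qc_check_standard",
    "dereplicate",
    "read_feature_table",
    "write_feature_table",
    "read_library",
]

#: Monoisotopic atomic masses (Da), CODATA/AME-derived reference values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of the proton (Da).  Adduct arithmetic uses the proton mass, not the
#: hydrogen-atom mass: [M+H]+ gains a proton and loses nothing else, so the
#: electron deficit is already accounted for.
PROTON_MASS = 1.007276466621

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_LOG = logging.getLogger(__name__)


@dataclass(frozen=True)
class Formula:
    """Elemental composition (C/H/N/O/S, extensible via the mass table)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``"C21H20O10"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text.strip()):
            if m.start() != pos or not m.group(0):
                break
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text.strip()) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(e for e in self.counts if e not in ("C", "H"))
        return "".join(
            f"{e}{self.counts[e] if self.counts[e] != 1 else ''}"
            for e in order
            if e in self.counts
        )

    def rdbe(self) -> float:
        """Ring-and-double-bond equivalents: C - H/2 + N/2 + 1."""
        c = self.counts.get("C", 0)
        h = self.counts.get("H", 0)
        n = self.counts.get("N", 0)
        return c - h / 2 + n / 2 + 1


def monoisotopic_mass(formula: Formula | str) -> float:
    """Neutral monoisotopic mass (Da) of a formula."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())


_ADDUCTS = {"[M+H]+": PROTON_MASS, "[M-H]-": -PROTON_MASS}


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct of a neutral molecule.

    Supported adducts are the protonated and deprotonated molecules,
    ``[M+H]+`` and ``[M-H]-`` (unicode minus accepted).
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    key = adduct.replace("−", "-").replace("‒", "-").replace("–", "-")
    if key not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; expected one of {sorted(_ADDUCTS)}")
    return neutral_mass + _ADDUCTS[key]


def default_adduct(polarity: str) -> str:
    """Default adduct per ionization polarity: [M+H]+ (P) / [M-H]- (N)."""
    p = polarity.strip().lower()
    if p in ("positive", "pos", "p", "+"):
        return "[M+H]+"
    if p in ("negative", "neg", "n", "-"):
        return "[M-H]-"
    raise ValueError(f"unknown polarity {polarity!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# molecular-formula prediction


@dataclass(frozen=True)
class FormulaConstraints:
    """Search space and heuristic filters for formula prediction.

    ``bounds`` maps element symbol -> maximum count (minimum 0).  The
    heuristic filters are the classic element-ratio and RDBE plausibility
    checks used for small-molecule formula assignment: H/C within
    ``hc_range``, O/C at most ``oc_max``, RDBE at least ``rdbe_min`` and
    integral for even-electron neutral molecules.
    """

    bounds: Mapping[str, int] = field(
        default_factory=lambda: {"C": 50, "H": 80, "N": 5, "O": 30, "S": 2}
    )
    hc_range: tuple[float, float] = (0.2, 3.1)
    oc_max: float = 1.2
    rdbe_min: float = 0.0
    require_integer_rdbe: bool = True

    def admits(self, f: Formula) -> bool:
        c = f.counts.get("C", 0)
        h = f.counts.get("H", 0)
        o = f.counts.get("O", 0)
        if c == 0:
            return False
        hc = h / c
        if not (self.hc_range[0] <= hc <= self.hc_range[1]):
            return False
        if o / c > self.oc_max:
            return False
        r = f.rdbe()
        if r < self.rdbe_min:
            return False
        if self.require_integer_rdbe and abs(r - round(r)) > 1e-9:
            return False
        return True


def predict_formula(
    mz: float,
    adduct: str,
    tol_ppm: float = 3.0,
    constraints: FormulaConstraints | None = None,
) -> list[tuple[Formula, float]]:
    """Enumerate candidate molecular formulas for an accurate mass.

    Exhaustively searches the element bounds, keeps candidates whose
    theoretical adduct m/z lies within ``tol_ppm`` of the query and which
    pass the heuristic filters, and returns (formula, ppm error) pairs
    sorted by \\|ppm error\\| (ties: fewer distinct elements, then fewer
    atoms).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    constraints = constraints or FormulaConstraints()
    bounds = {el: int(n) for el, n in constraints.bounds.items() if int(n) > 0}
    if not bounds or "C" not in bounds or "H" not in bounds:
        raise ValueError("constraint space must allow at least C and H")
    target = mz - _ADDUCTS[adduct.replace("−", "-")]
    window = mz * tol_ppm * 1e-6  # tolerance on the measured scale
    heavy = [el for el in ("S", "N", "O", "C") if el in bounds]
    m_h = MONOISOTOPIC_MASS["H"]

    out: list[tuple[Formula, float]] = []

    def recurse(i: int, counts: dict[str, int], mass: float) -> None:
        if mass > target + window:
            return
        if i == len(heavy):
            lo = (target - window - mass) / m_h
            hi = (target + window - mass) / m_h
            for h in range(max(0, int(np.ceil(lo - 1e-12))), min(bounds["H"], int(np.floor(hi + 1e-12))) + 1):
                f = Formula({**counts, "H": h})
                if not constraints.admits(f):
                    continue
                theo = adduct_mz(monoisotopic_mass(f), adduct)
                err = ppm_error(mz, theo)
                if abs(err) <= tol_ppm:
                    out.append((f, err))
            return
        el = heavy[i]
        m_el = MONOISOTOPIC_MASS[el]
        for n in range(0, bounds[el] + 1):
            new_mass = mass + n * m_el
            if new_mass > target + window:
                break
            recurse(i + 1, {**counts, el: n}, new_mass)

    recurse(0, {}, 0.0)
    out.sort(key=lambda fe: (abs(fe[1]), len(fe[0].counts), sum(fe[0].counts.values()), str(fe[0])))
    return out


# ---------------------------------------------------------------------------
# feature tables


@dataclass
class Feature:
    """One aligned LC-MS feature with per-sample peak areas."""

    feature_id: str
    mz: float
    rt: float
    polarity: str
    areas: dict[str, float]

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id!r}: m/z must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id!r}: retention time must be >= 0")
        default_adduct(self.polarity)  # validates


@dataclass
class FeatureTable:
    """Aligned feature table: metadata plus a features x samples area matrix."""

    features: list[Feature]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")
        for f in self.features:
            missing = set(self.sample_ids) - set(f.areas)
            if missing:
                raise ValueError(
                    f"feature {f.feature_id!r} lacks areas for samples {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def area_matrix(self) -> pd.DataFrame:
        """samples x features DataFrame of peak areas."""
        data = {f.feature_id: [f.areas[s] for s in self.sample_ids] for f in self.features}
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mz": [f.mz for f in self.features],
                "rt_min": [f.rt for f in self.features],
                "polarity": [f.polarity for f in self.features],
            }
        )
        areas = self.area_matrix().T.reset_index(drop=True)
        return pd.concat([meta, areas], axis=1)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read an MZmine-CSV-export-like delimited feature table."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["feature_id", "mz", "rt_min", "polarity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in required]
    features = [
        Feature(
            feature_id=str(row["feature_id"]),
            mz=float(row["mz"]),
            rt=float(row["rt_min"]),
            polarity=str(row["polarity"]),
            areas={s: float(row[s]) for s in sample_ids},
        )
        for row in df.to_dict("records")
    ]
    return FeatureTable(features=features, sample_ids=sample_ids)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curation


def remove_blank_features(
    table: FeatureTable, blank_ids: Sequence[str], threshold: float = 0.0
) -> FeatureTable:
    """Delete every feature detected in a solvent blank.

    A feature is considered detected in a blank when its area there exceeds
    ``threshold`` (default 0, i.e. any signal).  Blank columns are removed
    from the surviving table.
    """
    blank_ids = list(blank_ids)
    unknown = set(blank_ids) - set(table.sample_ids)
    if unknown:
        raise ValueError(f"unknown blank sample ids: {sorted(unknown)}")
    keep_samples = [s for s in table.sample_ids if s not in blank_ids]
    kept: list[Feature] = []
    for f in table.features:
        if any(f.areas[b] > threshold for b in blank_ids):
            continue
        kept.append(
            Feature(f.feature_id, f.mz, f.rt, f.polarity, {s: f.areas[s] for s in keep_samples})
        )
    return FeatureTable(features=kept, sample_ids=keep_samples)


@dataclass
class QcReport:
    """Outcome of the external-standard retention/mass check."""

    passed: bool
    matches: list[str]
    nearest_id: str | None
    nearest_rt: float | None
    nearest_mz: float | None
    expected_rt: float
    expected_mz: float


def qc_check_standard(
    table: FeatureTable,
    expected_rt: float = 11.38,
    rt_tol: float = 0.2,
    expected_mz: float = 609.2794,
    mz_tol_ppm: float = 3.0,
) -> QcReport:
    """Check that the external standard (reserpine) was recovered.

    Passes iff at least one feature falls within both the retention window
    (expected_rt +/- rt_tol, minutes) and the mass window (mz_tol_ppm around
    expected_mz).  Always returns a report; an empty table fails with no
    nearest candidate.
    """
    matches = [
        f.feature_id
        for f in table.features
        if abs(f.rt - expected_rt) <= rt_tol
        and abs(ppm_error(f.mz, expected_mz)) <= mz_tol_ppm
    ]
    nearest = None
    if table.features:
        nearest = min(
            table.features,
            key=lambda f: (abs(f.rt - expected_rt) / max(rt_tol, 1e-9))
            + abs(ppm_error(f.mz, expected_mz)) / max(mz_tol_ppm, 1e-9),
        )
    return QcReport(
        passed=bool(matches),
        matches=matches,
        nearest_id=nearest.feature_id if nearest else None,
        nearest_rt=nearest.rt if nearest else None,
        nearest_mz=nearest.mz if nearest else None,
        expected_rt=expected_rt,
        expected_mz=expected_mz,
    )


# ---------------------------------------------------------------------------
# dereplication


@dataclass
class Annotation:
    """Accurate-mass library match for one feature (confidence Level 3)."""

    feature_id: str
    compound: str
    formula: Formula | None
    theoretical_mz: float
    observed_mz: float
    ppm: float
    adduct: str
    level: str = "Level 3"


def read_library(path: str | Path) -> pd.DataFrame:
    """Read a compound library (columns: name, formula, neutral_mass, taxon).

    ``neutral_mass`` may be omitted when a formula is given; ``taxon`` is a
    semicolon-separated tag list used for taxonomy-aware filtering.
    """
    lib = pd.read_csv(path, sep=None, engine="python")
    if "name" not in lib.columns:
        raise ValueError("library must have a 'name' column")
    for col in ("formula", "neutral_mass", "taxon"):
        if col not in lib.columns:
            lib[col] = np.nan
    return lib


def dereplicate(
    table: FeatureTable,
    library: pd.DataFrame,
    tol_ppm: float = 3.0,
    taxon_filter: Sequence[str] | None = None,
) -> list[Annotation]:
    """Annotate features by accurate-mass lookup against a compound library.

    Each feature's observed m/z is compared with the theoretical m/z of each
    library compound under the default adduct of the feature's polarity;
    every match within ``tol_ppm`` is emitted.  ``taxon_filter`` restricts
    the candidate compounds to those sharing at least one taxon tag before
    matching (hits consistent with the studied genus/family are the ones
    treated as credible).  Entries with neither a mass nor a parsable
    formula are skipped.
    """
    candidates: list[tuple[str, Formula | None, float]] = []
    for row in library.to_dict("records"):
        name = str(row["name"])
        raw_taxon = row.get("taxon", np.nan)
        taxa = [] if pd.isna(raw_taxon) else str(raw_taxon).split(";")
        if taxon_filter is not None and not set(t.strip() for t in taxa) & set(taxon_filter):
            continue
        formula = None
        mass = np.nan
        raw_formula = row.get("formula", np.nan)
        if not pd.isna(raw_formula) and str(raw_formula).strip():
            try:
                formula = Formula.parse(str(raw_formula))
                mass = monoisotopic_mass(formula)
            except ValueError:
                formula = None
        raw_mass = row.get("neutral_mass", np.nan)
        if np.isnan(mass) and not pd.isna(raw_mass):
            mass = float(raw_mass)
        if np.isnan(mass):
            _LOG.warning("library entry %r has neither mass nor formula; skipped", name)
            continue
        candidates.append((name, formula, mass))

    annotations: list[Annotation] = []
    for f in table.features:
        adduct = default_adduct(f.polarity)
        for name, formula, mass in candidates:
            theo = adduct_mz(mass, adduct)
            err = ppm_error(f.mz, theo)
            if abs(err) <= tol_ppm:
                annotations.append(
                    Annotation(
                        feature_id=f.feature_id,
                        compound=name,
                        formula=formula,
                        theoretical_mz=theo,
                        observed_mz=f.mz,
                        ppm=err,
                        adduct=adduct,
                    )
                )
    return annotations
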