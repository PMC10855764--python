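"""Synthetic VOC-profile generator emulating the irradiated-cheese study design.

Real chromatograms for the study are not deposited, so every downstream
stage is exercised on synthetic data with the same statistical structure:

* per cheese, 45 non-irradiated samples plus 15 at each of 2.0, 4.0 and
  6.0 kGy (90 in total);
* 63 (Brie) / 79 (Camembert) VOCs partitioned into 12 chemical classes;
* class-level dose-response templates: radiolytic hydrocarbons (alkanes,
  alkenes, alkynes) and aldehydes increase monotonically with dose;
  alcohols, carboxylic acids, esters, methyl esters, ketones, lactones,
  sulfur compounds and aromatics rise to a maximum at 4.0 kGy and fall
  back at 6.0 kGy; packaging/processing contaminants ("other") are flat;
* multiplicative log-normal noise on positive areas (chromatographic
  variance is multiplicative, and zeros stay exactly zero);
* radiolytic hydrocarbons are structural zeros at dose 0 — they occur only
  in irradiated samples — except one configurable n-hexane-like alkane;
* only a subset of each responsive class carries the dose effect (the
  study's VIP marker lists cover ~15 of 63-79 VOCs); the generator records
  the ground-truth discriminant set.

Peak-level fixtures (retention times on an alkane ladder plus an internal
standard spike) and DoE response fixtures are also generated here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatography import (
    DEFAULT_IS_MZ,
    AlkaneLadder,
    FeatureTable,
    PeakRecord,
)
from .exceptions import ConfigurationError

Pattern = Literal["monotone_up", "peak_mid", "flat", "down"]

#: Dose levels of the study, in kilogray.
DEFAULT_DOSES = (0.0, 2.0, 4.0, 6.0)

#: VOCs per chemical class, Brie (63 compounds in 12 classes).
BRIE_CLASS_COUNTS: dict[str, int] = {
    "alcohols": 9,
    "aldehydes": 1,
    "alkanes": 6,
    "alkenes": 4,
    "aromatics": 1,
    "carboxylic_acids": 10,
    "esters": 2,
    "ketones": 10,
    "methyl_esters": 16,
    "other": 2,
    "sulfur_compounds": 1,
    "terpenes": 1,
}

#: VOCs per chemical class, Camembert (79 compounds in 12 classes).
CAMEMBERT_CLASS_COUNTS: dict[str, int] = {
    "alcohols": 12,
    "aldehydes": 4,
    "alkanes": 7,
    "alkenes": 4,
    "alkynes": 1,
    "aromatics": 2,
    "carboxylic_acids": 11,
    "ketones": 9,
    "methyl_esters": 16,
    "lactones": 2,
    "other": 4,
    "sulfur_compounds": 7,
}

#: Classes whose members are radiolytic: absent (exact zero) at dose 0.
IRRADIATION_ONLY_CLASSES = frozenset({"alkanes", "alkenes", "alkynes"})

#: Dose-response pattern per chemical class.
CLASS_PATTERNS: dict[str, Pattern] = {
    "alcohols": "peak_mid",
    "aldehydes": "monotone_up",
    "alkanes": "monotone_up",
    "alkenes": "monotone_up",
    "alkynes": "monotone_up",
    "aromatics": "peak_mid",
    "carboxylic_acids": "peak_mid",
    "esters": "peak_mid",
    "ketones": "peak_mid",
    "lactones": "peak_mid",
    "methyl_esters": "peak_mid",
    "other": "flat",
    "sulfur_compounds": "peak_mid",
    "terpenes": "monotone_up",
}

#: How many VOCs per class carry the dose effect by default, mirroring the
#: per-class composition of the study's VIP marker lists. ``None`` means
#: every member of the class responds (the radiolytic hydrocarbons do).
DEFAULT_MARKER_COUNTS: dict[str, int | None] = {
    "alcohols": 2,
    "aldehydes": 1,
    "alkanes": None,
    "alkenes": None,
    "alkynes": None,
    "aromatics": 1,
    "carboxylic_acids": 2,
    "esters": 1,
    "ketones": 3,
    "lactones": 1,
    "methyl_esters": 2,
    "other": 0,
    "sulfur_compounds": 1,
    "terpenes": 1,
}


@dataclass(frozen=True)
class DoseResponseTemplate:
    """Expected dose-response of one VOC chemical class.

    Parameters
    ----------
    class_name : chemical class label.
    pattern : ``monotone_up`` (linear in dose), ``peak_mid`` (quadratic
        with vertex at 4.0 kGy), ``flat``, or ``down`` (linear decrease).
    base_level : normalized-area scale of a responsive VOC at dose 0.
    effect_size : multiplicative fold-change at the pattern's maximum
        (>= 1 for monotone_up and peak_mid).
    noise_sigma : standard deviation of the log-scale noise (>= 0).
    n_markers : number of class members carrying the dose effect; ``None``
        means all of them. Non-responding members stay flat at base level.
    """

    class_name: str
    pattern: Pattern
    base_level: float = 1.0
    effect_size: float = 3.0
    noise_sigma: float = 0.25
    n_markers: int | None = None

    def __post_init__(self) -> None:
        if self.base_level <= 0:
            raise ConfigurationError("base_level must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        if self.pattern in ("monotone_up", "peak_mid") and self.effect_size < 1:
            raise ConfigurationError(
                f"effect_size must be >= 1 for {self.pattern}"
            )
        if self.n_markers is not None and self.n_markers < 0:
            raise ConfigurationError("n_markers must be non-negative")

    def expected_level(
        self, dose: float, max_dose: float = 6.0, structural_zero: bool = False
    ) -> float:
        """Noise-free expected normalized area at ``dose`` kGy."""
        if structural_zero:
            # absent below any irradiation; grows linearly with dose
            return self.base_level * self.effect_size * dose / max_dose
        if self.pattern == "flat":
            return self.base_level
        if self.pattern == "monotone_up":
            return self.base_level * (
                1.0 + (self.effect_size - 1.0) * dose / max_dose
            )
        if self.pattern == "peak_mid":
            # quadratic in dose with vertex at 4.0 kGy
            vertex = 4.0
            shape = 1.0 - ((dose - vertex) / vertex) ** 2
            return self.base_level * (1.0 + (self.effect_size - 1.0) * shape)
        if self.pattern == "down":
            return self.base_level * (1.0 - 0.5 * dose / max_dose)
        raise ConfigurationError(f"unknown pattern {self.pattern!r}")


def default_templates(
    effect_size: float = 3.0, noise_sigma: float = 0.25
) -> list[DoseResponseTemplate]:
    """The study-condition templates for all 14 class labels."""
    return [
        DoseResponseTemplate(
            class_name=name,
            pattern=CLASS_PATTERNS[name],
            base_level=1.0,
            effect_size=effect_size,
            noise_sigma=noise_sigma,
            n_markers=DEFAULT_MARKER_COUNTS[name],
        )
        for name in CLASS_PATTERNS
    ]


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Sampling design of one synthetic cheese study.

    Defaults reproduce the study layout: 45 control + 15 samples at each
    of 2.0/4.0/6.0 kGy, with the Brie or Camembert class composition.
    """

    cheese: Literal["brie", "camembert"] = "camembert"
    n_control: int = 45
    n_per_dose: int = 15
    doses: tuple[float, ...] = DEFAULT_DOSES
    class_counts: Mapping[str, int] | None = None
    seed: int = 0
    #: class containing the one VOC detectable at dose 0 despite being
    #: radiolytic (the n-hexane case); set to None to disable.
    structural_zero_exception: str | None = "alkanes"

    def resolved_class_counts(self) -> dict[str, int]:
        if self.class_counts is not None:
            counts = dict(self.class_counts)
        elif self.cheese == "brie":
            counts = dict(BRIE_CLASS_COUNTS)
        else:
            counts = dict(CAMEMBERT_CLASS_COUNTS)
        for name, k in counts.items():
            if k <= 0:
                raise ConfigurationError(
                    f"class {name!r} has non-positive count {k}"
                )
        return counts

    @property
    def nonzero_doses(self) -> tuple[float, ...]:
        return tuple(d for d in self.doses if d > 0)

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_per_dose * len(self.nonzero_doses)


def _sample_doses(config: SyntheticStudyConfig) -> np.ndarray:
    return np.concatenate(
        [np.zeros(config.n_control)]
        + [np.full(config.n_per_dose, d) for d in config.nonzero_doses]
    )


def generate_voc_table(
    config: SyntheticStudyConfig,
    templates: Sequence[DoseResponseTemplate] | None = None,
) -> FeatureTable:
    """Generate one cheese's samples x VOC table of IS-normalized areas.

    Every entry is the class template's expected level at the sample's
    dose times ``exp(Normal(0, noise_sigma))``. The returned table carries
    the ground-truth list of discriminant VOCs (effect-carrying members
    plus the irradiation-only structural zeros) in ``markers``.
    """
    if templates is None:
        templates = default_templates()
    counts = config.resolved_class_counts()
    by_class = {t.class_name: t for t in templates}
    missing = sorted(set(counts) - set(by_class))
    if missing:
        raise ConfigurationError(f"no template for classes {missing}")

    rng = np.random.default_rng(config.seed)
    doses = _sample_doses(config)
    max_dose = max(config.doses)
    n = len(doses)

    columns: list[str] = []
    classes: dict[str, str] = {}
    markers: list[str] = []
    blocks: list[np.ndarray] = []

    for class_name in sorted(counts):
        tmpl = by_class[class_name]
        k = counts[class_name]
        n_resp = k if tmpl.n_markers is None else min(tmpl.n_markers, k)
        irradiation_only = class_name in IRRADIATION_ONLY_CLASSES
        for j in range(k):
            name = f"{class_name}_{j + 1:02d}"
            columns.append(name)
            classes[name] = class_name
            responsive = j < n_resp
            structural = irradiation_only and not (
                j == 0 and config.structural_zero_exception == class_name
            )
            if structural:
                expected = np.array(
                    [
                        tmpl.expected_level(d, max_dose, structural_zero=True)
                        for d in doses
                    ]
                )
                markers.append(name)
            elif responsive:
                expected = np.array(
                    [tmpl.expected_level(d, max_dose) for d in doses]
                )
                if tmpl.pattern != "flat":
                    markers.append(name)
            else:
                expected = np.full(n, tmpl.base_level)
            noise = np.exp(rng.normal(0.0, tmpl.noise_sigma, size=n))
            blocks.append(expected * noise)

    sample_ids = [f"{config.cheese}_{i + 1:03d}" for i in range(n)]
    data = pd.DataFrame(
        np.column_stack(blocks), index=sample_ids, columns=columns
    )
    meta = pd.DataFrame(
        {"cheese": config.cheese, "dose_kgy": doses}, index=sample_ids
    )
    return FeatureTable(
        data=data,
        sample_meta=meta,
        compound_classes=pd.Series(classes, name="class"),
        markers=markers,
    )


# ---------------------------------------------------------------------------
# chromatogram-level peak fixture


@dataclass(frozen=True)
class PeakFixture:
    """Per-sample peak records with known ground truth for LRI recovery."""

    peaks_by_sample: dict[str, list[PeakRecord]]
    ladder: AlkaneLadder
    true_lri: dict[str, float]
    sample_meta: pd.DataFrame


def default_ladder() -> AlkaneLadder:
    """A C7-C30 ladder with mildly expanding inter-alkane spacing."""
    carbons = tuple(range(7, 31))
    rts = tuple(2.0 + 1.1 * (c - 7) + 0.01 * (c - 7) ** 2 for c in carbons)
    return AlkaneLadder(carbons=carbons, rts=rts)


def generate_peak_fixture(
    config: SyntheticStudyConfig,
    n_analytes: int = 10,
    is_area: float = 1_000.0,
    ladder: AlkaneLadder | None = None,
) -> PeakFixture:
    """Emit peak records whose retention times have known LRI values.

    Each sample carries one internal-standard peak (quantifier m/z 59) and
    ``n_analytes`` analyte peaks placed at fixed fractions of ladder
    intervals, so the ground-truth LRI of analyte ``i`` is exact by
    construction. Analyte areas are log-normal around the class-free base.
    """
    if ladder is None:
        ladder = default_ladder()
    rng = np.random.default_rng(config.seed)
    doses = _sample_doses(config)
    sample_ids = [f"{config.cheese}_{i + 1:03d}" for i in range(len(doses))]

    carbons = np.asarray(ladder.carbons)
    rts = np.asarray(ladder.rts)
    true_lri: dict[str, float] = {}
    analyte_rts: dict[str, float] = {}
    for i in range(n_analytes):
        seg = i % (len(carbons) - 1)
        frac = (i % 4) / 4.0  # 0, .25, .5, .75 of the interval
        rt = rts[seg] + frac * (rts[seg + 1] - rts[seg])
        name = f"analyte_{i + 1:02d}"
        analyte_rts[name] = float(rt)
        true_lri[name] = float(
            100.0 * (carbons[seg] + frac * (carbons[seg + 1] - carbons[seg]))
        )

    is_rt = float(rts[len(rts) // 2] + 0.123)  # anywhere inside the span
    peaks_by_sample: dict[str, list[PeakRecord]] = {}
    for sid in sample_ids:
        records = [
            PeakRecord(sid, "internal_standard", is_rt, DEFAULT_IS_MZ, is_area)
        ]
        for name, rt in analyte_rts.items():
            area = float(is_area * np.exp(rng.normal(0.0, 0.25)))
            records.append(PeakRecord(sid, name, rt, 60 + len(records), area))
        peaks_by_sample[sid] = records

    meta = pd.DataFrame(
        {"cheese": config.cheese, "dose_kgy": doses}, index=sample_ids
    )
    return PeakFixture(
        peaks_by_sample=peaks_by_sample,
        ladder=ladder,
        true_lri=true_lri,
        sample_meta=meta,
    )


# ---------------------------------------------------------------------------
# DoE response fixture


def generate_ccd_responses(
    design,
    truths: Sequence,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw response values for each design run from known truth surfaces.

    ``truths`` is one quadratic surface per response (Y1 total area, Y2
    VOC count); values are ``truth(run) + Normal(0, noise_sigma)``. With
    ``noise_sigma=0`` they equal the truth surface exactly.
    """
    coded = np.asarray(design.coded_runs, dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for r, surface in enumerate(truths):
        if surface.n_factors != coded.shape[1]:
            raise ConfigurationError(
                f"truth surface {r} expects {surface.n_factors} factors, "
                f"design has {coded.shape[1]}"
            )
        y = surface.predict(coded)
        if noise_sigma > 0:
            y = y + rng.normal(0.0, noise_sigma, size=len(y))
        out[f"y{r + 1}"] = y
    return pd.DataFrame(out, index=pd.RangeIndex(1, len(coded) + 1, name="run"))
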