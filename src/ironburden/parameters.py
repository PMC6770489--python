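"""Typed registry of model inputs.

Every quantity the pipeline consumes is defined here: the stratum grid
(gender x age class x menstrual/menopausal status), per-stratum population
counts, lognormal absorbed-iron intake fits with 95% confidence intervals,
normal absorbed-iron requirement distributions, the proportion of iron
deficiency that presents as iron-deficiency anemia, hemoglobin status
distributions, WHO anemia severity thresholds, and the shared disability
weights.  A national parameter set for metropolitan France (2007) ships with
the package as JSON and is the default input of the pipeline.

The stratum grid is irregular on purpose: males carry a merged 12-17 age
class, females split adolescence into 12-14 (assumed non-menstruating) and
15-17 (menstruating); postmenopausal strata exist only for 25-44, 45-64 and
65-74, and women 65-74 are all postmenopausal.  Seventeen strata in total.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "Gender",
    "MenstrualStatus",
    "StratumKey",
    "IntakeModel",
    "RequirementModel",
    "HemoglobinModel",
    "SeverityThresholds",
    "DisabilityWeight",
    "StratumParams",
    "ParameterSet",
    "ParameterError",
    "EXPECTED_STRATA",
    "STRATUM_ORDER",
    "SEVERITIES",
    "load_parameters",
    "total_population",
]

SEVERITIES = ("mild", "moderate", "severe")

MALE_AGE_CLASSES = ("3-6", "7-11", "12-17", "18-24", "25-44", "45-64", "65-74")
PREMENO_AGE_CLASSES = ("3-6", "7-11", "12-14", "15-17", "18-24", "25-44", "45-64")
POSTMENO_AGE_CLASSES = ("25-44", "45-64", "65-74")

#: (low, high) inclusive integer age bounds per age-class label.
AGE_BOUNDS = {
    "3-6": (3, 6),
    "7-11": (7, 11),
    "12-14": (12, 14),
    "15-17": (15, 17),
    "12-17": (12, 17),
    "18-24": (18, 24),
    "25-44": (25, 44),
    "45-64": (45, 64),
    "65-74": (65, 74),
}


class ParameterError(ValueError):
    """Raised when a parameter file is malformed or violates an invariant."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True, order=True)
class StratumKey:
    gender: str  # "male" | "female"
    age_class: str
    menstrual_status: str  # "not_applicable" | "premenopausal" | "postmenopausal"

    def __post_init__(self) -> None:
        _check(self.gender in ("male", "female"), f"unknown gender {self.gender!r}")
        _check(self.age_class in AGE_BOUNDS, f"unknown age class {self.age_class!r}")
        _check(
            self.menstrual_status in ("not_applicable", "premenopausal", "postmenopausal"),
            f"unknown menstrual status {self.menstrual_status!r}",
        )
        if self.gender == "male":
            _check(self.menstrual_status == "not_applicable",
                   f"male stratum {self} must have menstrual_status=not_applicable")
            _check(self.age_class in MALE_AGE_CLASSES,
                   f"males use the merged 12-17 class, not {self.age_class}")
        elif self.menstrual_status == "premenopausal":
            _check(self.age_class in PREMENO_AGE_CLASSES,
                   f"no premenopausal stratum for age class {self.age_class}")
        else:
            _check(self.menstrual_status == "postmenopausal",
                   f"female stratum {self} needs an explicit menstrual status")
            _check(self.age_class in POSTMENO_AGE_CLASSES,
                   f"no postmenopausal stratum for age class {self.age_class}")

    def label(self) -> str:
        if self.gender == "male":
            return f"male/{self.age_class}"
        return f"female/{self.age_class}/{self.menstrual_status}"


#: Canonical stratum ordering; the index doubles as the deterministic
#: per-stratum RNG spawn key, so results are reproducible stratum by stratum.
STRATUM_ORDER: tuple[StratumKey, ...] = tuple(
    [StratumKey("male", a, "not_applicable") for a in MALE_AGE_CLASSES]
    + [StratumKey("female", a, "premenopausal") for a in PREMENO_AGE_CLASSES]
    + [StratumKey("female", a, "postmenopausal") for a in POSTMENO_AGE_CLASSES]
)

EXPECTED_STRATA = frozenset(STRATUM_ORDER)


@dataclass(frozen=True)
class IntakeModel:
    """Lognormal absorbed-intake fit (log mg/day) with 95% CIs per parameter."""

    meanlog: float
    sdlog: float
    meanlog_ci: tuple[float, float]
    sdlog_ci: tuple[float, float]

    def __post_init__(self) -> None:
        _check(self.sdlog > 0, f"sdlog must be > 0, got {self.sdlog}")
        lo, hi = self.meanlog_ci
        _check(lo <= self.meanlog <= hi,
               f"meanlog {self.meanlog} outside its CI [{lo}, {hi}]")
        lo, hi = self.sdlog_ci
        _check(0 < lo <= self.sdlog <= hi,
               f"sdlog {self.sdlog} outside its CI [{lo}, {hi}]")


@dataclass(frozen=True)
class RequirementModel:
    """Normal distribution of absorbed-iron requirement (mg/day).

    sd = 0 is admitted as the degenerate limit (every draw equals the mean),
    in which exact closed-form results exist; real parameter sets use sd > 0.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        _check(self.mean > 0, f"requirement mean must be > 0, got {self.mean}")
        _check(self.sd >= 0, f"requirement sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class HemoglobinModel:
    """Normal distribution of hemoglobin status (g/dL)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        _check(10.0 <= self.mean <= 20.0,
               f"hemoglobin mean {self.mean} outside plausible range [10, 20] g/dL")
        _check(self.sd > 0, f"hemoglobin sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class SeverityThresholds:
    """WHO hemoglobin cut-offs (g/dL).  Anemia is Hb < mild_upper; bands are
    severe [0, severe_upper), moderate [severe_upper, moderate_upper),
    mild [moderate_upper, mild_upper)."""

    mild_upper: float
    moderate_upper: float
    severe_upper: float

    def __post_init__(self) -> None:
        _check(self.severe_upper < self.moderate_upper < self.mild_upper,
               f"thresholds must be ordered severe < moderate < mild, got {self}")


@dataclass(frozen=True)
class DisabilityWeight:
    """Health-loss weight of one anemia severity level, in [0, 1]."""

    severity: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        _check(self.severity in SEVERITIES, f"unknown severity {self.severity!r}")
        _check(0.0 <= self.mean <= 1.0, f"weight mean {self.mean} outside [0, 1]")
        _check(self.sd >= 0, f"weight sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class StratumParams:
    key: StratumKey
    population: int
    intake: IntakeModel
    requirement: RequirementModel
    prop_ida: float
    hemoglobin: HemoglobinModel
    thresholds: SeverityThresholds

    def __post_init__(self) -> None:
        _check(self.population >= 0, f"{self.key.label()}: negative population")
        _check(0.0 <= self.prop_ida <= 1.0,
               f"{self.key.label()}: prop_ida {self.prop_ida} outside [0, 1]")


@dataclass(frozen=True)
class ParameterSet:
    strata: dict[StratumKey, StratumParams]
    disability_weights: dict[str, DisabilityWeight]
    absorption_coefficients: dict[str, float]
    total_reference_population: int
    name: str = "unnamed"

    def __post_init__(self) -> None:
        present = set(self.strata)
        missing = EXPECTED_STRATA - present
        _check(not missing,
               "missing strata: " + ", ".join(sorted(k.label() for k in missing)))
        extra = present - EXPECTED_STRATA
        _check(not extra,
               "unexpected strata: " + ", ".join(sorted(k.label() for k in extra)))
        _check(set(self.disability_weights) == set(SEVERITIES),
               "disability weights must cover mild, moderate and severe")
        means = [self.disability_weights[s].mean for s in SEVERITIES]
        _check(means[0] < means[1] < means[2],
               "disability weights must increase with severity")
        _check(self.total_reference_population > 0,
               "total_reference_population must be > 0")
        for coef in self.absorption_coefficients.values():
            _check(0 < coef <= 1, f"absorption coefficient {coef} outside (0, 1]")

    def __iter__(self) -> Iterator[StratumParams]:
        """Iterate strata in canonical order."""
        return (self.strata[k] for k in STRATUM_ORDER)

    def stratum_population_total(self) -> int:
        return sum(s.population for s in self.strata.values())

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total_reference_population": self.total_reference_population,
            "absorption_coefficients": dict(self.absorption_coefficients),
            "disability_weights": {
                s: {"mean": w.mean, "sd": w.sd}
                for s, w in self.disability_weights.items()
            },
            "strata": [
                {
                    "gender": sp.key.gender,
                    "age_class": sp.key.age_class,
                    "menstrual_status": sp.key.menstrual_status,
                    "population": sp.population,
                    "intake": {
                        "meanlog": sp.intake.meanlog,
                        "meanlog_ci": list(sp.intake.meanlog_ci),
                        "sdlog": sp.intake.sdlog,
                        "sdlog_ci": list(sp.intake.sdlog_ci),
                    },
                    "requirement": {"mean": sp.requirement.mean, "sd": sp.requirement.sd},
                    "prop_ida": sp.prop_ida,
                    "hemoglobin": {"mean": sp.hemoglobin.mean, "sd": sp.hemoglobin.sd},
                    "thresholds": {
                        "mild_upper": sp.thresholds.mild_upper,
                        "moderate_upper": sp.thresholds.moderate_upper,
                        "severe_upper": sp.thresholds.severe_upper,
                    },
                }
                for sp in self
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    def to_csv(self, path: str | Path) -> None:
        """Human-inspectable flat mirror of the stratum table."""
        cols = ["gender", "age_class", "status", "pop", "meanlog", "meanlog_lo",
                "meanlog_hi", "sdlog", "sdlog_lo", "sdlog_hi", "req_mean",
                "req_sd", "prop_ida", "hb_mean", "hb_sd", "thr_mild",
                "thr_moderate", "thr_severe"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for sp in self:
                writer.writerow([
                    sp.key.gender, sp.key.age_class, sp.key.menstrual_status,
                    sp.population,
                    sp.intake.meanlog, *sp.intake.meanlog_ci,
                    sp.intake.sdlog, *sp.intake.sdlog_ci,
                    sp.requirement.mean, sp.requirement.sd, sp.prop_ida,
                    sp.hemoglobin.mean, sp.hemoglobin.sd,
                    sp.thresholds.mild_upper, sp.thresholds.moderate_upper,
                    sp.thresholds.severe_upper,
                ])


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ParameterError(f"{context}: missing field {key!r}")
    return mapping[key]


def _parse_stratum(raw: dict) -> StratumParams:
    ctx = f"stratum {raw.get('gender')}/{raw.get('age_class')}/{raw.get('menstrual_status')}"
    key = StratumKey(
        _require(raw, "gender", ctx),
        _require(raw, "age_class", ctx),
        _require(raw, "menstrual_status", ctx),
    )
    intake_raw = _require(raw, "intake", ctx)
    req_raw = _require(raw, "requirement", ctx)
    hb_raw = _require(raw, "hemoglobin", ctx)
    thr_raw = _require(raw, "thresholds", ctx)
    return StratumParams(
        key=key,
        population=int(_require(raw, "population", ctx)),
        intake=IntakeModel(
            meanlog=float(_require(intake_raw, "meanlog", ctx)),
            sdlog=float(_require(intake_raw, "sdlog", ctx)),
            meanlog_ci=tuple(_require(intake_raw, "meanlog_ci", ctx)),
            sdlog_ci=tuple(_require(intake_raw, "sdlog_ci", ctx)),
        ),
        requirement=RequirementModel(
            mean=float(_require(req_raw, "mean", ctx)),
            sd=float(_require(req_raw, "sd", ctx)),
        ),
        prop_ida=float(_require(raw, "prop_ida", ctx)),
        hemoglobin=HemoglobinModel(
            mean=float(_require(hb_raw, "mean", ctx)),
            sd=float(_require(hb_raw, "sd", ctx)),
        ),
        thresholds=SeverityThresholds(
            mild_upper=float(_require(thr_raw, "mild_upper", ctx)),
            moderate_upper=float(_require(thr_raw, "moderate_upper", ctx)),
            severe_upper=float(_require(thr_raw, "severe_upper", ctx)),
        ),
    )


def load_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter set.

    With no argument, loads the packaged French 2007 national configuration.
    Raises :class:`ParameterError` naming the offending field on malformed
    input, and listing missing strata on incomplete coverage.
    """
    if config_path is None:
        source = resources.files("ironburden").joinpath("data/france_2007.json")
        raw = json.loads(source.read_text())
    else:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(f"parameter config not found: {path}")
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParameterError(f"cannot parse {path}: {exc}") from exc

    strata_raw = _require(raw, "strata", "config")
    strata = {}
    for entry in strata_raw:
        sp = _parse_stratum(entry)
        if sp.key in strata:
            raise ParameterError(f"duplicate stratum {sp.key.label()}")
        strata[sp.key] = sp
    weights_raw = _require(raw, "disability_weights", "config")
    weights = {
        s: DisabilityWeight(s, float(_require(w, "mean", f"weight {s}")),
                            float(_require(w, "sd", f"weight {s}")))
        for s, w in weights_raw.items()
    }
    return ParameterSet(
        strata=strata,
        disability_weights=weights,
        absorption_coefficients={
            k: float(v)
            for k, v in _require(raw, "absorption_coefficients", "config").items()
        },
        total_reference_population=int(
            _require(raw, "total_reference_population", "config")),
        name=raw.get("name", "unnamed"),
    )


def total_population(ps: ParameterSet) -> int:
    """Reference denominator for per-100,000 rates.

    This is deliberately *not* the sum of stratum populations: the model
    covers ages 3-74 and excludes pregnant women, while rates are expressed
    per 100,000 of the whole national population.
    """
    return ps.total_reference_population
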