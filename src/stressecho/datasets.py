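"""Synthetic cohort generation.

The study cohort (529 patients referred for dobutamine stress echocardiography,
82 positive / 447 negative) is not publicly deposited; only its class-conditional
summary statistics are printed.  This module generates cohorts with exactly that
statistical structure -- per-class prevalences for binary risk factors and
medications, a three-level smoking distribution, and Gaussian age/weight -- so
that every downstream stage (encoding, mutual-information ranking, class-weighted
classification) can be exercised and tested.

Variables are drawn conditionally independently given the outcome class: the
published tables report only class-conditional marginals, so no dependence
structure can be matched.  See ``docs/methods.md`` for what this does and does
not emulate.

A second generator, :func:`generate_planted_cohort`, builds cohorts with known
ground truth (designated informative vs pure-noise binary features) for
validating ranking recovery and the class-weighting behaviour.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableDef",
    "ClassConditionalSpec",
    "PlantedTruth",
    "SMOKING_LABELS",
    "OUTCOME_COLUMN",
    "default_cohort_spec",
    "generate_cohort",
    "generate_planted_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

SMOKING_LABELS = ("nonsmoker", "ex-smoker", "smoker")
OUTCOME_COLUMN = "outcome"
POSITIVE, NEGATIVE = "positive", "negative"

#: Physiological floors for continuous draws (truncation keeps invariants).
DEFAULT_FLOORS = {"age": 18.0, "weight": 30.0}


@dataclass(frozen=True)
class VariableDef:
    """One clinical variable: a name and its measurement kind."""

    name: str
    kind: str  # {"binary", "categorical3", "continuous"}
    category_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("binary", "categorical3", "continuous"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical3" and len(self.category_labels) != 3:
            raise ValueError(f"{self.name}: categorical3 needs exactly 3 labels")


@dataclass
class ClassConditionalSpec:
    """Per-class distribution parameters for every variable in a cohort.

    ``params[name]`` maps class label ("positive"/"negative") to:

    * binary       -> prevalence probability in [0, 1]
    * categorical3 -> probability vector of length 3 summing to 1
    * continuous   -> (mean, sd) in the variable's units
    """

    variables: list[VariableDef]
    params: dict[str, dict[str, object]]
    class_sizes: tuple[int, int]  # (n_positive, n_negative)
    name: str = "cohort"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        for v in self.variables:
            if v.name not in self.params:
                raise ValueError(f"missing parameters for {v.name}")
            for cls in (POSITIVE, NEGATIVE):
                if cls not in self.params[v.name]:
                    raise ValueError(f"{v.name}: missing class {cls}")
                p = self.params[v.name][cls]
                if v.kind == "binary":
                    if not 0.0 <= float(p) <= 1.0:
                        raise ValueError(f"{v.name}: prevalence {p} outside [0,1]")
                elif v.kind == "categorical3":
                    vec = np.asarray(p, dtype=float)
                    if vec.shape != (3,) or abs(vec.sum() - 1.0) > 1e-12:
                        raise ValueError(f"{v.name}: probabilities must sum to 1")
                else:
                    mean, sd = p
                    if not sd > 0:
                        raise ValueError(f"{v.name}: SD must be > 0")
        if any(n < 0 for n in self.class_sizes):
            raise ValueError("class sizes must be nonnegative")

    def variable(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def drop(self, name: str) -> "ClassConditionalSpec":
        """Return a copy without the named variable."""
        return ClassConditionalSpec(
            variables=[v for v in self.variables if v.name != name],
            params={k: v for k, v in self.params.items() if k != name},
            class_sizes=self.class_sizes,
            name=self.name,
        )

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "class_sizes": {"positive": self.class_sizes[0], "negative": self.class_sizes[1]},
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    **({"labels": list(v.category_labels)} if v.kind == "categorical3" else {}),
                    "positive": _yamlify(self.params[v.name][POSITIVE]),
                    "negative": _yamlify(self.params[v.name][NEGATIVE]),
                }
                for v in self.variables
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ClassConditionalSpec":
        doc = yaml.safe_load(text)
        variables, params = [], {}
        for entry in doc["variables"]:
            kind = entry["kind"]
            v = VariableDef(entry["name"], kind, tuple(entry.get("labels", ())))
            variables.append(v)
            pos, neg = entry["positive"], entry["negative"]
            if kind == "continuous":
                pos, neg = tuple(pos), tuple(neg)
            params[v.name] = {POSITIVE: pos, NEGATIVE: neg}
        sizes = doc["class_sizes"]
        return cls(variables, params, (sizes["positive"], sizes["negative"]), doc.get("name", "cohort"))


def _yamlify(p):
    if isinstance(p, (tuple, np.ndarray)):
        return [float(x) for x in p]
    return float(p)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted cohort: which features carry class signal."""

    informative_features: frozenset
    noise_features: frozenset
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.informative_features & self.noise_features:
            raise ValueError("informative and noise feature sets must be disjoint")


# ---------------------------------------------------------------------------
# Published cohort parameters
# ---------------------------------------------------------------------------

# (positive count, negative count) with class sizes (82, 447); smoking as
# (nonsmoker, ex-smoker, smoker) counts.
_FULL_COUNTS = {
    "sex_male": (61, 188),
    "hypertension": (42, 264),
    "hypercholesterolemia": (50, 263),
    "diabetes": (19, 80),
    "family_history": (35, 188),
    "prior_cad": (40, 83),
    "beta_blocker": (58, 223),
    "calcium_channel_blocker": (22, 115),
    "ace_arb": (59, 199),
    "antiplatelet": (64, 280),
    "nitrate": (36, 123),
    "statin": (59, 255),
    "diuretic": (23, 106),
}
_FULL_SMOKING = {POSITIVE: (40, 24, 18), NEGATIVE: (290, 83, 74)}
_FULL_CONTINUOUS = {
    "age": {POSITIVE: (62.92, 10.56), NEGATIVE: (60.93, 12.06)},
    "weight": {POSITIVE: (83.06, 15.88), NEGATIVE: (80.45, 17.49)},
}
_FULL_SIZES = (82, 447)

_NOCAD_COUNTS = {
    "sex_male": (33, 147),
    "hypertension": (25, 216),
    "hypercholesterolemia": (33, 219),
    "diabetes": (6, 67),
    "family_history": (17, 132),
    "beta_blocker": (28, 166),
    "calcium_channel_blocker": (9, 89),
    "ace_arb": (32, 148),
    "antiplatelet": (34, 216),
    "nitrate": (24, 95),
    "statin": (29, 201),
    "diuretic": (12, 87),
}
# The published negative-class smoking counts (227, 13, 65) sum to 305 rather
# than the class size 364; the vector is renormalized over its own total.
_NOCAD_SMOKING = {POSITIVE: (17, 13, 12), NEGATIVE: (227, 13, 65)}
_NOCAD_CONTINUOUS = {
    "age": {POSITIVE: (64.28, 9.80), NEGATIVE: (60.96, 12.20)},
    "weight": {POSITIVE: (80.31, 13.18), NEGATIVE: (80.46, 17.37)},
}
_NOCAD_SIZES = (42, 364)

#: Declared variable order (risk factors then medications).
_VARIABLE_ORDER = [
    "sex_male", "age", "weight", "hypertension", "hypercholesterolemia",
    "smoking", "diabetes", "family_history", "prior_cad",
    "beta_blocker", "calcium_channel_blocker", "ace_arb", "antiplatelet",
    "nitrate", "statin", "diuretic",
]


def default_cohort_spec(variant: str = "full") -> ClassConditionalSpec:
    """Class-conditional parameters of the study cohort.

    Parameters
    ----------
    variant : {"full", "no_prior_cad"}
        ``full`` encodes the whole 529-patient cohort (82 positive, 447
        negative).  ``no_prior_cad`` encodes the 406-patient subset with no
        prior ischaemic heart disease (42 positive, 364 negative); it has no
        ``prior_cad`` variable.

    Binary prevalences are the published count divided by the class size
    (e.g. P(male | positive) = 61/82 for the full cohort); continuous
    variables use the published mean and SD.
    """
    if variant == "full":
        counts, smoking, continuous, sizes = (
            _FULL_COUNTS, _FULL_SMOKING, _FULL_CONTINUOUS, _FULL_SIZES)
    elif variant == "no_prior_cad":
        counts, smoking, continuous, sizes = (
            _NOCAD_COUNTS, _NOCAD_SMOKING, _NOCAD_CONTINUOUS, _NOCAD_SIZES)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'full' or 'no_prior_cad'")

    n_pos, n_neg = sizes
    variables, params = [], {}
    for name in _VARIABLE_ORDER:
        if name == "smoking":
            variables.append(VariableDef("smoking", "categorical3", SMOKING_LABELS))
            params["smoking"] = {
                cls: tuple(np.asarray(smoking[cls], dtype=float) / sum(smoking[cls]))
                for cls in (POSITIVE, NEGATIVE)
            }
        elif name in continuous:
            variables.append(VariableDef(name, "continuous"))
            params[name] = dict(continuous[name])
        elif name in counts:
            variables.append(VariableDef(name, "binary"))
            cp, cn = counts[name]
            params[name] = {POSITIVE: cp / n_pos, NEGATIVE: cn / n_neg}
        # 'prior_cad' is absent from the no_prior_cad tables and is skipped.
    return ClassConditionalSpec(variables, params, sizes, name=variant)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_cohort(
    spec: ClassConditionalSpec,
    n_positive: int,
    n_negative: int,
    seed: int,
    floors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a cohort table from class-conditional distributions.

    Outcome labels are assigned (``n_positive`` positive rows, ``n_negative``
    negative rows, order shuffled by ``seed``), never sampled, so class sizes
    are exact.  Each variable is drawn independently given the row's class.
    Continuous draws are truncated below at a physiological floor
    (18 years for age, 30 kg for weight by default).
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("row counts must be nonnegative")
    floors = {**DEFAULT_FLOORS, **(floors or {})}
    rng = np.random.default_rng(seed)

    outcome = np.array([POSITIVE] * n_positive + [NEGATIVE] * n_negative, dtype=object)
    rng.shuffle(outcome)
    n = len(outcome)
    is_pos = outcome == POSITIVE

    columns: dict[str, np.ndarray] = {}
    for v in spec.variables:
        p = spec.params[v.name]
        if v.kind == "binary":
            probs = np.where(is_pos, p[POSITIVE], p[NEGATIVE])
            columns[v.name] = (rng.random(n) < probs).astype(int)
        elif v.kind == "categorical3":
            col = np.empty(n, dtype=object)
            for cls, mask in ((POSITIVE, is_pos), (NEGATIVE, ~is_pos)):
                k = int(mask.sum())
                if k:
                    idx = rng.choice(3, size=k, p=np.asarray(p[cls], dtype=float))
                    col[mask] = np.asarray(v.category_labels, dtype=object)[idx]
            columns[v.name] = col
        else:
            mean = np.where(is_pos, p[POSITIVE][0], p[NEGATIVE][0])
            sd = np.where(is_pos, p[POSITIVE][1], p[NEGATIVE][1])
            draws = rng.normal(mean, sd)
            floor = floors.get(v.name, np.finfo(float).tiny)
            columns[v.name] = np.maximum(draws, floor)

    table = pd.DataFrame(columns, columns=[v.name for v in spec.variables])
    table[OUTCOME_COLUMN] = outcome
    return table


def generate_planted_cohort(
    n_per_class: int,
    n_informative: int,
    n_noise: int,
    prevalence_gap: float = 0.5,
    seed: int = 0,
    n_positive: int | None = None,
    n_negative: int | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Cohort with known informative and pure-noise binary features.

    Informative features have class-conditional prevalences ``0.5 +/- gap/2``
    (higher in the positive class); noise features have prevalence 0.5 in both
    classes.  ``n_positive``/``n_negative`` override the balanced
    ``n_per_class`` sizes, e.g. to build the 15%-positive imbalanced cohorts
    used to study minority-class weighting.
    """
    if n_informative + n_noise < 1:
        raise ValueError("need at least one feature")
    if not 0.0 < prevalence_gap <= 0.8:
        raise ValueError("prevalence_gap must be in (0, 0.8]")
    n_pos = n_per_class if n_positive is None else n_positive
    n_neg = n_per_class if n_negative is None else n_negative

    hi, lo = 0.5 + prevalence_gap / 2, 0.5 - prevalence_gap / 2
    variables, params, effects = [], {}, {}
    informative = [f"signal_{i + 1}" for i in range(n_informative)]
    noise = [f"noise_{i + 1}" for i in range(n_noise)]
    for name in informative:
        variables.append(VariableDef(name, "binary"))
        params[name] = {POSITIVE: hi, NEGATIVE: lo}
        effects[name] = prevalence_gap
    for name in noise:
        variables.append(VariableDef(name, "binary"))
        params[name] = {POSITIVE: 0.5, NEGATIVE: 0.5}
    spec = ClassConditionalSpec(variables, params, (n_pos, n_neg), name="planted")
    truth = PlantedTruth(frozenset(informative), frozenset(noise), effects)
    return generate_cohort(spec, n_pos, n_neg, seed), truth


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path_or_buf, header_comment: str | None = None) -> None:
    """Write a cohort as UTF-8 comma-delimited CSV (optional ``#`` header)."""
    text = cohort.to_csv(index=False)
    if header_comment:
        text = "".join(f"# {line}\n" for line in header_comment.splitlines()) + text
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_cohort_csv(path_or_buf) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    table = pd.read_csv(path_or_buf, comment="#")
    validate_cohort(table)
    return table


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort-table invariants; raise ``ValueError`` on violation."""
    if OUTCOME_COLUMN not in cohort.columns:
        raise ValueError("cohort is missing the outcome column")
    if cohort.isna().any().any():
        raise ValueError("cohort contains missing values")
    bad = set(cohort[OUTCOME_COLUMN].unique()) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    if "smoking" in cohort.columns:
        bad = set(cohort["smoking"].unique()) - set(SMOKING_LABELS)
        if bad:
            raise ValueError(f"unknown smoking labels: {sorted(bad)}")
    for col in ("age", "weight"):
        if col in cohort.columns:
            vals = cohort[col].to_numpy(dtype=float)
            if not (np.isfinite(vals).all() and (vals > 0).all()):
                raise ValueError(f"{col} must be finite and positive")
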