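"""Domain types and I/O for the arm-level aggregate survival corpus.

The unit of data is a digitized Kaplan-Meier point: a (time, survival
fraction) pair read off a published curve for one trial arm.  Arms carry a
sample size and a covariate profile (drug, biomarker, therapy type, ...);
studies group arms; the :class:`Corpus` is the full meta-analytic table.

On disk a corpus is a plain CSV with one row per (arm, time) pair.  The
binomial standard error of each fraction is derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ArmObservation",
    "CovariateProfile",
    "Arm",
    "Corpus",
    "CorpusValidationError",
    "SchemaError",
    "read_corpus",
    "write_corpus",
    "summarize_corpus",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]

THERAPY_TYPES = frozenset({"monotherapy", "combination"})
DRUGS = frozenset({"olaparib", "niraparib", "rucaparib"})
BIOMARKERS = frozenset({"BRCAm", "BRCAwt", "HRD_positive"})
PLATINUM = frozenset({"sensitive", "partially_resistant"})
PARTNERS = frozenset({"none", "chemotherapy", "bevacizumab", "cediranib"})

REQUIRED_COLUMNS = (
    "study_id",
    "arm_id",
    "n",
    "therapy_type",
    "drug",
    "biomarker",
    "platinum",
    "partner",
    "time_months",
    "surv_fraction",
)
OPTIONAL_COLUMNS = ("ecog0_pct", "median_age", "blinded")


class CorpusValidationError(ValueError):
    """A corpus (or file being read) violates a domain invariant."""


class SchemaError(ValueError):
    """The input table is missing a required column."""


@dataclass
class ArmObservation:
    """One digitized KM point: survival fraction at a time, with its SE."""

    time: float
    obs_fraction: float
    se: float = 0.0
    pred_fraction: float | None = None

    def validate(self, where: str = "") -> None:
        if not self.time > 0:
            raise CorpusValidationError(f"{where}: time must be > 0, got {self.time}")
        if not 0.0 <= self.obs_fraction <= 1.0:
            raise CorpusValidationError(
                f"{where}: surv_fraction must be in [0,1], got {self.obs_fraction}"
            )
        if self.se < 0:
            raise CorpusValidationError(f"{where}: se must be >= 0")


@dataclass(frozen=True)
class CovariateProfile:
    """Arm-level covariates: treatment, biomarker and design descriptors.

    ``ecog0_pct`` (percent of patients with ECOG performance status 0),
    ``median_age`` (years) and ``blinded`` may be missing (None); blanks
    propagate to the covariate engine, which imputes by the patient-weighted
    median.  ``partner`` is ``"none"`` exactly when the arm is monotherapy.
    """

    therapy_type: str
    drug: str
    biomarker: str
    platinum: str = "sensitive"
    partner: str = "none"
    ecog0_pct: float | None = None
    median_age: float | None = None
    blinded: bool | None = None

    def __post_init__(self) -> None:
        for name, val, allowed in (
            ("therapy_type", self.therapy_type, THERAPY_TYPES),
            ("drug", self.drug, DRUGS),
            ("biomarker", self.biomarker, BIOMARKERS),
            ("platinum", self.platinum, PLATINUM),
            ("partner", self.partner, PARTNERS),
        ):
            if val not in allowed:
                raise CorpusValidationError(
                    f"{name}={val!r} not in {sorted(allowed)}"
                )
        if (self.partner == "none") != (self.therapy_type == "monotherapy"):
            raise CorpusValidationError(
                "partner must be 'none' iff therapy_type is 'monotherapy' "
                f"(got therapy_type={self.therapy_type}, partner={self.partner})"
            )

    def get(self, name: str):
        return getattr(self, name)


@dataclass
class Arm:
    """One trial arm: sample size, covariates, and its KM observations."""

    study_id: str
    arm_id: str
    n: int
    covariates: CovariateProfile
    observations: list[ArmObservation] = field(default_factory=list)

    def validate(self) -> None:
        where = f"study {self.study_id} arm {self.arm_id}"
        if self.n < 1:
            raise CorpusValidationError(f"{where}: n must be >= 1, got {self.n}")
        if not self.observations:
            raise CorpusValidationError(f"{where}: arm has no observations")
        times = [o.time for o in self.observations]
        for i, obs in enumerate(self.observations):
            obs.validate(f"{where} row {i}")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise CorpusValidationError(
                f"{where}: observation times must be strictly increasing"
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([o.obs_fraction for o in self.observations])


@dataclass
class Corpus:
    """The full meta-analytic table: arms grouped by study."""

    arms: list[Arm]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.arms:
            raise CorpusValidationError("corpus has no arms")
        seen: set[tuple[str, str]] = set()
        for arm in self.arms:
            key = (arm.study_id, arm.arm_id)
            if key in seen:
                raise CorpusValidationError(
                    f"duplicate arm id {arm.arm_id!r} in study {arm.study_id!r}"
                )
            seen.add(key)
            arm.validate()

    @property
    def studies(self) -> dict[str, list[Arm]]:
        """Arms grouped by study id, preserving first-appearance order."""
        out: dict[str, list[Arm]] = {}
        for arm in self.arms:
            out.setdefault(arm.study_id, []).append(arm)
        return out

    @property
    def study_ids(self) -> list[str]:
        return list(self.studies)

    @property
    def n_patients(self) -> int:
        return sum(a.n for a in self.arms)

    @property
    def n_observations(self) -> int:
        return sum(len(a.observations) for a in self.arms)

    def subset(self, keep: Iterable[Arm]) -> "Corpus":
        keep = list(keep)
        return Corpus(arms=[replace(a) for a in keep], meta=dict(self.meta))


def _profile_from_row(row: Mapping) -> CovariateProfile:
    def opt_float(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return float(v)

    def opt_bool(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return str(v).strip().lower() in {"true", "1", "yes"}

    return CovariateProfile(
        therapy_type=str(row["therapy_type"]),
        drug=str(row["drug"]),
        biomarker=str(row["biomarker"]),
        platinum=str(row["platinum"]),
        partner=str(row["partner"]),
        ecog0_pct=opt_float(row.get("ecog0_pct")),
        median_age=opt_float(row.get("median_age")),
        blinded=opt_bool(row.get("blinded")),
    )


def read_corpus(path, schema: Mapping[str, str] | None = None) -> Corpus:
    """Read a corpus from a delimited text table.

    ``schema`` optionally maps canonical column names to the names used in
    the file.  Rows are grouped into arms by (study_id, arm_id), ordered by
    time within arm; each observation's binomial SE is derived from its
    fraction and the arm's sample size.
    """
    from .fitting import residual_se  # local import to avoid a cycle

    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    arms: list[Arm] = []
    for (study_id, arm_id), grp in df.groupby(["study_id", "arm_id"], sort=False):
        grp = grp.sort_values("time_months", kind="stable")
        n = int(grp["n"].iloc[0])
        profile = _profile_from_row(grp.iloc[0].to_dict())
        observations = []
        for idx, row in grp.iterrows():
            frac = float(row["surv_fraction"])
            if not 0.0 <= frac <= 1.0:
                raise CorpusValidationError(
                    f"study {study_id} arm {arm_id} row {idx}: "
                    f"surv_fraction {frac} outside [0,1]"
                )
            observations.append(
                ArmObservation(
                    time=float(row["time_months"]),
                    obs_fraction=frac,
                    se=residual_se(frac, n),
                )
            )
        arms.append(
            Arm(
                study_id=str(study_id),
                arm_id=str(arm_id),
                n=n,
                covariates=profile,
                observations=observations,
            )
        )
    corpus = Corpus(arms=arms)
    corpus.validate()
    return corpus


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    """Flatten a corpus to the one-row-per-(arm, time) table."""
    rows = []
    for arm in corpus.arms:
        cov = arm.covariates
        for obs in arm.observations:
            rows.append(
                {
                    "study_id": arm.study_id,
                    "arm_id": arm.arm_id,
                    "n": arm.n,
                    "therapy_type": cov.therapy_type,
                    "drug": cov.drug,
                    "biomarker": cov.biomarker,
                    "platinum": cov.platinum,
                    "partner": cov.partner,
                    "ecog0_pct": cov.ecog0_pct,
                    "median_age": cov.median_age,
                    "blinded": cov.blinded,
                    "time_months": obs.time,
                    "surv_fraction": obs.obs_fraction,
                }
            )
    return pd.DataFrame(rows)


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus as CSV in the same schema ``read_corpus`` accepts."""
    corpus.validate()
    # %.17g guarantees float64 round-trips bit-exactly through text
    corpus_to_frame(corpus).to_csv(path, index=False, float_format="%.17g")


def summarize_corpus(corpus: Corpus) -> pd.DataFrame:
    """Patient totals by drug, biomarker, therapy type and platinum status.

    Each patient is counted once per arm via the arm's ``n``.  Returns a
    tidy table with columns (dimension, level, patients).
    """
    corpus.validate()
    rows = []
    for dim in ("drug", "biomarker", "therapy_type", "platinum"):
        totals: dict[str, int] = {}
        for arm in corpus.arms:
            level = arm.covariates.get(dim)
            totals[level] = totals.get(level, 0) + arm.n
        for level in sorted(totals):
            rows.append({"dimension": dim, "level": level, "patients": totals[level]})
    return pd.DataFrame(rows)


def group_totals(corpus: Corpus, dimension: str) -> dict[str, int]:
    """Patient totals for one covariate dimension as a plain dict."""
    df = summarize_corpus(corpus)
    sub = df[df["dimension"] == dimension]
    return dict(zip(sub["level"], sub["patients"]))
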