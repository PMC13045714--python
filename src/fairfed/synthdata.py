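"""Synthetic consortium fixtures and survival simulators.

``generate_consortium_fixtures`` materialises five head-and-neck-cancer node
directories whose marginal distributions reproduce a published consortium
case-mix table cell-for-cell: per-variable category counts, mean age to one
decimal with the exact printed range, exact deceased counts, the model-cohort
sizes implied by the eligibility filter, and the radiomics-linkage counts.
Each node deliberately uses a *different* schema dialect — column names,
category codings, which variables exist at all — so the semantic annotation
layer has real work to do.  Joint structure beyond the published marginals is
sampled freely subject to the declared constraints (metastatic/Mx subjects
sit outside the oropharynx subgroup; radiomics records attach to the declared
number of eligible subjects).  An internal audit re-tabulates every written
CSV against its profile and fails loudly on any mismatch, so a downstream
discrepancy always implicates the pipeline rather than the fixtures.

``simulate_cox_data`` is the parametric test-bed generator: Weibull baseline
hazard with proportional effects ``h(t|x) = h0(t) exp(beta'x)`` and
independent censoring, fully seeded.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ProfileError

# canonical variable keys -> consortium variable labels
VAR_LABELS = {
    "sex": "Sex",
    "t": "Tumour stage",
    "n": "Nodal stage",
    "m": "Metastasis stage",
    "stage": "Overall stage (7th ed.)",
    "site": "Tumour location",
    "hpv": "HPV status",
    "treat": "Radiotherapy type",
    "vital": "Survival status",
}

RADIOMICS_LABELS = [
    "GTV volume",
    "GTV surface area",
    "GTV sphericity",
    "GTV intensity mean",
    "GTV texture entropy",
]

# risk contribution of the T category in the fixture survival model
_T_RISK = {"T1": 0.0, "T2": 0.3, "T3": 0.6, "T4": 0.9, "T4a": 0.9, "T4b": 1.1, "Tx": 0.45}


@dataclass(frozen=True)
class CategoricalDef:
    """One categorical column of a node dialect."""

    column: str
    codes: dict[str, str]  # canonical label -> local code
    counts: dict[str, int]  # canonical label -> target count
    missing: int = 0
    ordinal: bool = False


@dataclass(frozen=True)
class RadiomicsDef:
    id_column: str
    columns: tuple[str, str, str, str, str]
    n_linked: int  # eligible subjects carrying radiomics
    n_extra: int = 0  # additional non-eligible subjects carrying radiomics


@dataclass(frozen=True)
class NodeFixtureProfile:
    node_id: str
    n: int
    events: int
    age_mean: float
    age_min: int
    age_max: int
    id_column: str
    id_format: str
    age_column: str
    surv_column: str
    column_order: tuple[str, ...]  # dialect order of canonical keys
    categorical: dict[str, CategoricalDef]
    radiomics: RadiomicsDef

    def validate(self) -> None:
        for key, cdef in self.categorical.items():
            if key == "vital":
                continue
            total = sum(cdef.counts.values()) + cdef.missing
            if total != self.n:
                raise ProfileError(
                    f"{self.node_id}/{key}: counts+missing = {total} != sample size {self.n}"
                )
        site = self.categorical["site"]
        oro = site.counts.get("Oropharynx", 0)
        m = self.categorical["m"]
        n_m1mx = m.counts.get("M1", 0) + m.counts.get("Mx", 0)
        if n_m1mx > self.n - oro:
            raise ProfileError(f"{self.node_id}: cannot place M1/Mx outside oropharynx subgroup")
        eligible = oro  # M1/Mx live outside the subgroup; treatment covers everyone
        if self.radiomics.n_linked > eligible:
            raise ProfileError(
                f"{self.node_id}: radiomics linkage {self.radiomics.n_linked} exceeds eligible {eligible}"
            )
        if self.events >= self.n or self.events < 1:
            raise ProfileError(f"{self.node_id}: implausible event count {self.events}")


# --------------------------------------------------------------------------
# the five shipped profiles
# --------------------------------------------------------------------------

def consortium_profiles() -> list[NodeFixtureProfile]:
    """The five shipped node profiles (marginals of the consortium table)."""
    hn1 = NodeFixtureProfile(
        node_id="HN1", n=137, events=74, age_mean=61.9, age_min=44, age_max=83,
        id_column="id", id_format="HN1-{:03d}",
        age_column="age", surv_column="survival_days",
        column_order=("sex", "t", "n", "m", "stage", "site", "hpv", "treat", "vital"),
        categorical={
            "sex": CategoricalDef("biological_sex", {"Female": "F", "Male": "M"},
                                  {"Female": 26, "Male": 111}),
            "t": CategoricalDef("clin_t", {f"T{i}": f"T{i}" for i in range(1, 5)},
                                {"T1": 35, "T2": 32, "T3": 24, "T4": 46}, ordinal=True),
            "n": CategoricalDef("clin_n", {f"N{i}": f"N{i}" for i in range(4)},
                                {"N0": 60, "N1": 16, "N2": 58, "N3": 3}, ordinal=True),
            "m": CategoricalDef("clin_m", {"M0": "M0", "M1": "M1"},
                                {"M0": 136, "M1": 1}, ordinal=True),
            "stage": CategoricalDef("ajcc7", {"I": "I", "II": "II", "III": "III", "IV": "IV"},
                                    {"I": 24, "II": 11, "III": 23, "IV": 79}, ordinal=True),
            "site": CategoricalDef("tumour_site", {"Oropharynx": "oropharynx", "Larynx": "larynx"},
                                   {"Oropharynx": 88, "Larynx": 49}),
            "hpv": CategoricalDef("hpv_status",
                                  {"Positive": "positive", "Negative": "negative", "Unknown": "unknown"},
                                  {"Positive": 23, "Negative": 58, "Unknown": 56}),
            "treat": CategoricalDef("treatment", {"Radiotherapy": "RT", "Chemoradiotherapy": "CRT"},
                                    {"Radiotherapy": 100, "Chemoradiotherapy": 37}),
            "vital": CategoricalDef("status", {"Censored": "alive", "Deceased": "dead"}, {}),
        },
        radiomics=RadiomicsDef("id", ("shape_volume", "shape_surface", "shape_sphericity",
                                      "intensity_mean", "texture_entropy"), n_linked=80, n_extra=6),
    )
    hnscc = NodeFixtureProfile(
        node_id="HNSCC", n=492, events=116, age_mean=57.8, age_min=28, age_max=87,
        id_column="patient_id", id_format="HNSCC-{:04d}",
        age_column="age_years", surv_column="followup_days",
        column_order=("sex", "t", "n", "m", "stage", "site", "hpv", "treat", "vital"),
        categorical={
            "sex": CategoricalDef("gender", {"Female": "2", "Male": "1"},
                                  {"Female": 69, "Male": 423}),
            "t": CategoricalDef("t_cat", {f"T{i}": str(i) for i in range(1, 5)},
                                {"T1": 92, "T2": 203, "T3": 117, "T4": 80}, ordinal=True),
            "n": CategoricalDef("n_cat", {f"N{i}": str(i) for i in range(4)},
                                {"N0": 45, "N1": 53, "N2": 378, "N3": 16}, ordinal=True),
            # the M1 code exists in this dialect (mapped), it just has zero subjects
            "m": CategoricalDef("m_cat", {"M0": "0", "M1": "1"}, {"M0": 492, "M1": 0}, ordinal=True),
            "stage": CategoricalDef("stage_7ed", {"I": "1", "II": "2", "III": "3", "IV": "4"},
                                    {"I": 3, "II": 16, "III": 67, "IV": 406}, ordinal=True),
            "site": CategoricalDef("subsite", {"Oropharynx": "OPX"}, {"Oropharynx": 492}),
            "hpv": CategoricalDef("p16_status", {"Positive": "pos", "Negative": "neg", "Unknown": "unk"},
                                  {"Positive": 248, "Negative": 44, "Unknown": 200}),
            "treat": CategoricalDef("regimen",
                                    {"Radiotherapy": "rt_alone", "Chemoradiotherapy": "chemo_rt"},
                                    {"Radiotherapy": 57, "Chemoradiotherapy": 435}),
            "vital": CategoricalDef("vital_status", {"Censored": "0", "Deceased": "1"}, {}),
        },
        radiomics=RadiomicsDef("patient_id", ("Vol_mm3", "Surface_mm2", "Sphericity",
                                              "Mean_HU", "Entropy_GLCM"), n_linked=396),
    )
    opc = NodeFixtureProfile(
        node_id="OPC", n=606, events=259, age_mean=60.5, age_min=33, age_max=89,
        id_column="ID", id_format="OPC-{:04d}",
        age_column="Age", surv_column="OS_days",
        column_order=("sex", "t", "n", "m", "stage", "site", "hpv", "treat", "vital"),
        categorical={
            "sex": CategoricalDef("Sex", {"Female": "Female", "Male": "Male"},
                                  {"Female": 125, "Male": 481}),
            # this dialect splits T4 into T4a/T4b: the consortium's T4 count
            # (122) is only recoverable through subclass closure
            "t": CategoricalDef("T_stage",
                                {"T1": "T1", "T2": "T2", "T3": "T3", "T4a": "T4a", "T4b": "T4b"},
                                {"T1": 103, "T2": 198, "T3": 183, "T4a": 85, "T4b": 37}, ordinal=True),
            "n": CategoricalDef("N_stage", {f"N{i}": f"N{i}" for i in range(4)},
                                {"N0": 101, "N1": 61, "N2": 397, "N3": 47}, ordinal=True),
            "m": CategoricalDef("M_stage", {"M0": "M0"}, {"M0": 606}, ordinal=True),
            "stage": CategoricalDef("Overall_stage",
                                    {"I": "Stage I", "II": "Stage II", "III": "Stage III", "IV": "Stage IV"},
                                    {"I": 11, "II": 38, "III": 85, "IV": 472}, ordinal=True),
            "site": CategoricalDef("Primary_site", {"Oropharynx": "Oropharynx"}, {"Oropharynx": 606}),
            "hpv": CategoricalDef("HPV", {"Positive": "HPV+", "Negative": "HPV-", "Unknown": "Not tested"},
                                  {"Positive": 356, "Negative": 143, "Unknown": 107}),
            "treat": CategoricalDef("Treatment", {"Radiotherapy": "RT alone", "Chemoradiotherapy": "ChemoRT"},
                                    {"Radiotherapy": 309, "Chemoradiotherapy": 297}),
            "vital": CategoricalDef("Status", {"Censored": "Alive", "Deceased": "Dead"}, {}),
        },
        radiomics=RadiomicsDef("ID", ("original_shape_VoxelVolume", "original_shape_SurfaceArea",
                                      "original_shape_Sphericity", "original_firstorder_Mean",
                                      "original_glcm_Entropy"), n_linked=582),
    )
    head_neck = NodeFixtureProfile(
        node_id="HEAD-NECK", n=298, events=56, age_mean=63.3, age_min=18, age_max=90,
        id_column="subject", id_format="HEAD-NECK-{:03d}",
        age_column="age_at_diagnosis", surv_column="followup_time_days",
        column_order=("sex", "t", "n", "m", "stage", "site", "hpv", "treat", "vital"),
        categorical={
            "sex": CategoricalDef("sex_code", {"Female": "f", "Male": "m"},
                                  {"Female": 71, "Male": 227}),
            "t": CategoricalDef("tstage",
                                {"T1": "T1", "T2": "T2", "T3": "T3", "T4": "T4", "Tx": "TX"},
                                {"T1": 39, "T2": 109, "T3": 94, "T4": 46, "Tx": 10}, ordinal=True),
            "n": CategoricalDef("nstage", {f"N{i}": f"N{i}" for i in range(4)},
                                {"N0": 59, "N1": 40, "N2": 180, "N3": 19}, ordinal=True),
            "m": CategoricalDef("mstage", {"M0": "M0", "M1": "M1", "Mx": "MX"},
                                {"M0": 294, "M1": 0, "Mx": 4}, ordinal=True),
            "stage": CategoricalDef("overall_stage",
                                    {"I": "stage1", "II": "stage2", "III": "stage3", "IV": "stage4",
                                     "Unspecified": "unspecified"},
                                    {"I": 4, "II": 27, "III": 61, "IV": 204, "Unspecified": 2},
                                    ordinal=True),
            "site": CategoricalDef("primary_site",
                                   {"Nasopharynx": "nasopharynx", "Oropharynx": "oropharynx",
                                    "Hypopharynx": "hypopharynx", "Larynx": "larynx", "Unknown": "unknown"},
                                   {"Nasopharynx": 28, "Oropharynx": 203, "Hypopharynx": 13,
                                    "Larynx": 45, "Unknown": 9}),
            "hpv": CategoricalDef("hpv_p16", {"Positive": "pos", "Negative": "neg", "Unknown": "not_assessed"},
                                  {"Positive": 78, "Negative": 46, "Unknown": 174}),
            "treat": CategoricalDef("treatment_modality",
                                    {"Radiotherapy": "radiotherapy", "Chemoradiotherapy": "chemoradiation"},
                                    {"Radiotherapy": 48, "Chemoradiotherapy": 250}),
            "vital": CategoricalDef("death_observed", {"Censored": "no", "Deceased": "yes"}, {}),
        },
        radiomics=RadiomicsDef("subject", ("rad_volume", "rad_surface", "rad_sphericity",
                                           "rad_mean_intensity", "rad_entropy"),
                               n_linked=203, n_extra=12),
    )
    hn3 = NodeFixtureProfile(
        node_id="HN3", n=165, events=88, age_mean=62.6, age_min=29, age_max=84,
        id_column="pt_nr", id_format="HN3-{:03d}",
        age_column="leeftijd", surv_column="os_dagen",
        # no overall-stage column at all at this node
        column_order=("sex", "t", "n", "m", "site", "hpv", "treat", "vital"),
        categorical={
            "sex": CategoricalDef("geslacht", {"Female": "V", "Male": "M"},
                                  {"Female": 43, "Male": 122}),
            "t": CategoricalDef("cT", {f"T{i}": str(i) for i in range(1, 5)},
                                {"T1": 14, "T2": 31, "T3": 68, "T4": 52}, ordinal=True),
            "n": CategoricalDef("cN", {f"N{i}": str(i) for i in range(4)},
                                {"N0": 48, "N1": 45, "N2": 54, "N3": 18}, ordinal=True),
            "m": CategoricalDef("cM", {"M0": "0", "M1": "1"}, {"M0": 165, "M1": 0}, ordinal=True),
            # 7 subjects have an empty tumour-location cell (missing, not Unknown)
            "site": CategoricalDef("lokatie",
                                   {"Oropharynx": "orofarynx", "Hypopharynx": "hypofarynx", "Larynx": "larynx"},
                                   {"Oropharynx": 63, "Hypopharynx": 31, "Larynx": 64}, missing=7),
            "hpv": CategoricalDef("hpv_uitslag",
                                  {"Positive": "positief", "Negative": "negatief", "Unknown": "onbekend"},
                                  {"Positive": 34, "Negative": 29, "Unknown": 102}),
            "treat": CategoricalDef("behandeling", {"Radiotherapy": "RT", "Chemoradiotherapy": "chemoRT"},
                                    {"Radiotherapy": 104, "Chemoradiotherapy": 61}),
            "vital": CategoricalDef("overleden", {"Censored": "nee", "Deceased": "ja"}, {}),
        },
        radiomics=RadiomicsDef("pt_nr", ("vol", "opp", "bolvormigheid", "gem_intensiteit", "entropie"),
                               n_linked=60, n_extra=8),
    )
    return [hn1, hnscc, opc, head_neck, hn3]


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _shuffled_labels(cdef: CategoricalDef, n: int, rng: np.random.Generator) -> np.ndarray:
    labels: list[str] = []
    for lab, c in cdef.counts.items():
        labels.extend([lab] * c)
    labels.extend([""] * cdef.missing)
    if len(labels) != n:
        raise ProfileError(f"column {cdef.column}: {len(labels)} labels for {n} rows")
    arr = np.array(labels, dtype=object)
    rng.shuffle(arr)
    return arr


def _adjust_ages(n: int, mean: float, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Integer ages: truncated-normal draw (sd 10 y), then adjusted so the
    rounded mean matches to 1 dp and min/max equal the printed range."""
    ages = np.clip(np.rint(rng.normal(mean, 10.0, size=n)), lo, hi).astype(int)
    ages[0], ages[1] = lo, hi
    target = int(round(mean * n))
    if not (lo * n <= target <= hi * n):
        raise ProfileError(f"age mean {mean} unreachable within range {lo}-{hi}")
    idx = 2
    while ages.sum() != target:
        delta = target - ages.sum()
        i = 2 + (idx % (n - 2))
        step = 1 if delta > 0 else -1
        if lo <= ages[i] + step <= hi:
            ages[i] += step
        idx += 1
    return ages


def _simulate_survival(
    lp: np.ndarray, events_target: int, rng: np.random.Generator,
    *, shape: float = 1.1, scale: float = 2200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull event times under proportional hazards, uniform censoring, and
    an administrative cutoff chosen so the event count is exact."""
    n = len(lp)
    u = rng.uniform(size=n)
    T = scale * np.power(-np.log(u) / np.exp(lp), 1.0 / shape)
    C = rng.uniform(400.0, 4500.0, size=n)
    natural = np.sort(T[T <= C])
    if len(natural) < events_target:
        raise ProfileError(
            f"only {len(natural)} natural events for a target of {events_target}; "
            "survival-model constants infeasible for this profile"
        )
    tau = float(natural[events_target - 1])
    event = (T <= C) & (T <= tau)
    assert int(event.sum()) == events_target
    time = np.where(event, T, np.minimum(C, tau))
    days = np.maximum(np.rint(time).astype(int), 1)
    return days, event.astype(int)


def _fixture_lp(frame: dict[str, np.ndarray], ages: np.ndarray) -> np.ndarray:
    """Prognostic linear predictor wiring the fixture's survival times to its
    case mix (stage, age, HPV, treatment)."""
    t_risk = np.array([_T_RISK.get(lab, 0.45) for lab in frame["t"]])
    hpv_neg = (frame["hpv"] == "Negative").astype(float)
    crt = (frame["treat"] == "Chemoradiotherapy").astype(float)
    return 0.28 * t_risk + 0.018 * (ages - 60) + 0.35 * hpv_neg - 0.2 * crt


def generate_radiomics_features(
    subjects: list[str], seed: int, lp: np.ndarray | None = None, id_column: str = "id",
    columns: tuple[str, ...] = ("f1", "f2", "f3", "f4", "f5"),
) -> pd.DataFrame:
    """Five strictly positive, lognormal-skewed GTV features, partially
    correlated with the prognostic linear predictor when one is supplied."""
    rng = np.random.default_rng(seed)
    n = len(subjects)
    if lp is None or np.std(lp) == 0:
        z = np.zeros(n)
    else:
        z = (lp - np.mean(lp)) / np.std(lp)
    mus = [10.0, 8.5, -0.3, 4.5, 1.5]
    sigmas = [0.8, 0.6, 0.15, 0.3, 0.4]
    rhos = [0.5, 0.45, -0.3, 0.2, 0.35]
    data = {id_column: subjects}
    for col, mu, sg, rho in zip(columns, mus, sigmas, rhos):
        eps = rng.normal(size=n)
        latent = rho * z + np.sqrt(1 - rho**2) * eps
        data[col] = np.round(np.exp(mu + sg * latent), 4)
    return pd.DataFrame(data)


def _node_metadata(profile: NodeFixtureProfile) -> dict:
    cols = {profile.id_column: {"kind": "identifier"}}
    cols[profile.age_column] = {"kind": "continuous", "unit": "years"}
    for key in profile.column_order:
        cdef = profile.categorical[key]
        kind = "categorical_ordinal" if cdef.ordinal else "categorical_nominal"
        cols[cdef.column] = {"kind": kind, "description": VAR_LABELS[key].lower()}
    cols[profile.surv_column] = {"kind": "continuous", "unit": "days"}
    return {"columns": cols}


def _node_mappings(profile: NodeFixtureProfile) -> dict:
    classes = {profile.age_column: "Age in years", profile.surv_column: "Survival days"}
    values: dict[str, dict[str, str]] = {}
    for key in profile.column_order:
        cdef = profile.categorical[key]
        classes[cdef.column] = VAR_LABELS[key]
        values[cdef.column] = {code: label for label, code in cdef.codes.items()}
    return {
        "node_id": profile.node_id,
        "classes": classes,
        "values": values,
        "units": {profile.age_column: "Year", profile.surv_column: "Day"},
    }


def _radiomics_metadata(profile: NodeFixtureProfile) -> dict:
    cols = {profile.radiomics.id_column: {"kind": "identifier"}}
    for col in profile.radiomics.columns:
        cols[col] = {"kind": "continuous"}
    return {"columns": cols}


def _radiomics_mappings(profile: NodeFixtureProfile) -> dict:
    classes = dict(zip(profile.radiomics.columns, RADIOMICS_LABELS))
    return {"node_id": profile.node_id, "classes": classes}


def generate_node_fixture(profile: NodeFixtureProfile, out_dir: Path, seed: int) -> None:
    profile.validate()
    rng = np.random.default_rng([seed, zlib.crc32(profile.node_id.encode())])
    n = profile.n
    ids = [profile.id_format.format(i + 1) for i in range(n)]

    labels: dict[str, np.ndarray] = {}
    labels["site"] = _shuffled_labels(profile.categorical["site"], n, rng)
    # metastatic / Mx subjects are placed outside the oropharynx subgroup
    mdef = profile.categorical["m"]
    m_special = [lab for lab in ("M1", "Mx") for _ in range(mdef.counts.get(lab, 0))]
    m_col = np.array(["M0"] * n, dtype=object)
    if m_special:
        non_oro = np.flatnonzero(labels["site"] != "Oropharynx")
        chosen = rng.choice(non_oro, size=len(m_special), replace=False)
        for pos, lab in zip(chosen, m_special):
            m_col[pos] = lab
    labels["m"] = m_col
    for key in profile.column_order:
        if key in ("site", "m", "vital"):
            continue
        labels[key] = _shuffled_labels(profile.categorical[key], n, rng)

    ages = _adjust_ages(n, profile.age_mean, profile.age_min, profile.age_max, rng)
    lp = _fixture_lp(labels, ages)
    days, event = _simulate_survival(lp, profile.events, rng)
    labels["vital"] = np.where(event == 1, "Deceased", "Censored").astype(object)

    # encode the dialect
    data = {profile.id_column: ids, profile.age_column: ages}
    for key in profile.column_order:
        cdef = profile.categorical[key]
        codes = dict(cdef.codes)
        data[cdef.column] = [codes[lab] if lab else "" for lab in labels[key]]
    data[profile.surv_column] = days
    clinical = pd.DataFrame(data)

    eligible_mask = (labels["site"] == "Oropharynx") & (labels["m"] != "M1")
    eligible_idx = np.flatnonzero(eligible_mask)
    other_idx = np.flatnonzero(~eligible_mask)
    linked = rng.choice(eligible_idx, size=profile.radiomics.n_linked, replace=False)
    n_extra = min(profile.radiomics.n_extra, len(other_idx))
    extra = rng.choice(other_idx, size=n_extra, replace=False) if n_extra else np.array([], dtype=int)
    rad_rows = np.sort(np.concatenate([linked, extra]))
    rad_subjects = [ids[i] for i in rad_rows]
    rad_seed = int(rng.integers(0, 2**31 - 1))
    radiomics = generate_radiomics_features(
        rad_subjects, rad_seed, lp[rad_rows],
        id_column=profile.radiomics.id_column, columns=profile.radiomics.columns,
    )

    out_dir.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(out_dir / "clinical.csv", index=False)
    radiomics.to_csv(out_dir / "radiomics.csv", index=False)
    for name, payload in [
        ("clinical_metadata.yaml", _node_metadata(profile)),
        ("clinical_mappings.yaml", _node_mappings(profile)),
        ("radiomics_metadata.yaml", _radiomics_metadata(profile)),
        ("radiomics_mappings.yaml", _radiomics_mappings(profile)),
    ]:
        (out_dir / name).write_text(yaml.safe_dump(payload, sort_keys=False, allow_unicode=True), encoding="utf-8")
    audit_node_fixture(profile, out_dir)


def audit_node_fixture(profile: NodeFixtureProfile, node_dir: Path) -> None:
    """Re-tabulate the written CSVs against the profile; raise on mismatch."""
    df = pd.read_csv(node_dir / "clinical.csv", dtype=str, keep_default_na=False)

    def fail(msg: str):
        raise ProfileError(f"fixture audit failed for {profile.node_id}: {msg}")

    if len(df) != profile.n:
        fail(f"{len(df)} rows != {profile.n}")
    for key in profile.column_order:
        cdef = profile.categorical[key]
        col = df[cdef.column]
        if key == "vital":
            dead = (col == cdef.codes["Deceased"]).sum()
            if dead != profile.events:
                fail(f"deceased count {dead} != {profile.events}")
            continue
        tallies = col.value_counts().to_dict()
        for lab, target in cdef.counts.items():
            got = tallies.get(cdef.codes[lab], 0)
            if got != target:
                fail(f"{cdef.column}[{lab}] count {got} != {target}")
        miss = (col == "").sum()
        if miss != cdef.missing:
            fail(f"{cdef.column} missing {miss} != {cdef.missing}")
    ages = df[profile.age_column].astype(int)
    if round(ages.mean(), 1) != profile.age_mean:
        fail(f"mean age {ages.mean():.4f} !~ {profile.age_mean}")
    if ages.min() != profile.age_min or ages.max() != profile.age_max:
        fail(f"age range {ages.min()}-{ages.max()} != {profile.age_min}-{profile.age_max}")
    # joint constraint: M1/Mx never inside the oropharynx subgroup
    site_codes = profile.categorical["site"].codes
    oro_code = site_codes.get("Oropharynx")
    m_cdef = profile.categorical["m"]
    special_codes = {m_cdef.codes[lab] for lab in ("M1", "Mx") if lab in m_cdef.codes}
    bad = df[(df[profile.categorical["site"].column] == oro_code)
             & (df[m_cdef.column].isin(special_codes))]
    if len(bad):
        fail("M1/Mx subject inside oropharynx subgroup")
    rad = pd.read_csv(node_dir / "radiomics.csv", dtype=str, keep_default_na=False)
    eligible_ids = set(df[(df[profile.categorical["site"].column] == oro_code)
                          & (~df[m_cdef.column].isin({m_cdef.codes.get("M1")}))][profile.id_column])
    linked = len(set(rad[profile.radiomics.id_column]) & eligible_ids)
    if linked != profile.radiomics.n_linked:
        fail(f"radiomics-linked eligible count {linked} != {profile.radiomics.n_linked}")
    feats = rad[list(profile.radiomics.columns)].astype(float)
    if (feats <= 0).any().any():
        fail("non-positive radiomics feature value")


def generate_consortium_fixtures(
    out_dir: str | Path, seed: int = 42, profiles: list[NodeFixtureProfile] | None = None
) -> list[Path]:
    """Generate all node fixture directories; returns their paths."""
    out_dir = Path(out_dir)
    dirs = []
    for profile in profiles or consortium_profiles():
        d = out_dir / profile.node_id
        generate_node_fixture(profile, d, seed)
        dirs.append(d)
    return dirs


# --------------------------------------------------------------------------
# parametric survival simulator (test harness for the federated Cox engine)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationRecipe:
    """Weibull proportional-hazards data-generating process."""

    sizes: tuple[int, ...]
    beta: tuple[float, ...]
    shape: float = 1.5
    scale: float = 1.0
    censor_scale: float = 2.0  # exponential censoring mean
    covariate_kinds: tuple[str, ...] | None = None  # "normal" | "binary"
    round_times: int | None = None  # decimals; induces event-time ties
    seed: int = 0


def simulate_cox_data(recipe: SimulationRecipe) -> list[pd.DataFrame]:
    """One survival table per node: ``T ~ Weibull`` with hazard
    ``h0(t) exp(beta'x)``, independent exponential censoring."""
    rng = np.random.default_rng(recipe.seed)
    beta = np.asarray(recipe.beta, dtype=float)
    p = len(beta)
    kinds = recipe.covariate_kinds or ("normal",) * p
    frames = []
    for n in recipe.sizes:
        cols = []
        for kind in kinds:
            if kind == "binary":
                cols.append(rng.integers(0, 2, size=n).astype(float))
            else:
                cols.append(rng.normal(size=n))
        X = np.column_stack(cols) if p else np.zeros((n, 0))
        lp = X @ beta
        u = rng.uniform(size=n)
        T = recipe.scale * np.power(-np.log(u) / np.exp(lp), 1.0 / recipe.shape)
        C = rng.exponential(recipe.censor_scale, size=n)
        time = np.minimum(T, C)
        if recipe.round_times is not None:
            time = np.round(time, recipe.round_times) + 10.0 ** (-recipe.round_times - 2)
        df = pd.DataFrame({"time": time, "event": (T <= C).astype(int)})
        for j in range(p):
            df[f"x{j + 1}"] = X[:, j]
        frames.append(df)
    return frames


def hub_from_frames(frames: dict[str, pd.DataFrame], *, k_min: int = 1, audit_path=None):
    """Convenience: an in-process federation over in-memory survival tables."""
    from .federation import FederationHub
    from .node import DataStation
    from .vocab import ConsortiumVocabulary

    vocab = ConsortiumVocabulary.load()
    stations = {
        nid: DataStation.from_frame(nid, df, vocab=vocab) for nid, df in frames.items()
    }
    return FederationHub(stations, k_min=k_min, audit_path=audit_path)
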