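"""Federated prognostic modelling: clinical (C), radiomics (R) and combined
(CR) Cox models for overall survival, trained without any patient-level data
leaving a node.

Run:  python examples/03_federated_cox.py
"""

import tempfile
from pathlib import Path

from fairfed import (
    ConsortiumVocabulary,
    DataStation,
    FederationHub,
    compute_linear_predictor,
    cox_fit,
    eligibility_filter,
    fit_cr_model,
    fit_transforms,
    generate_consortium_fixtures,
    node_concordance,
)

workdir = Path(tempfile.mkdtemp())
generate_consortium_fixtures(workdir, seed=42)
vocab = ConsortiumVocabulary.load()
stations = {p.name: DataStation.from_directory(p, vocab) for p in sorted(workdir.iterdir())}
hub = FederationHub(stations, k_min=1)

# model cohort: primary oropharyngeal, not M1, treated with (chemo)radiotherapy
c_sizes = eligibility_filter(hub, store="c_cohort", k_min=1)
r_sizes = eligibility_filter(hub, store="r_cohort", require_radiomics=True, k_min=1)
print(f"clinical-model cohort per node : {c_sizes} (total {sum(c_sizes.values())})")
print(f"radiomics-linked cohort        : {r_sizes} (total {sum(r_sizes.values())})")

# C-Model: clinical case-mix factors
c_model = cox_fit(hub, ["Age in years", "Sex", "Tumour stage", "HPV status",
                        "Radiotherapy type"], "c_cohort")
print(f"\nC-Model ({c_model.n} subjects, {c_model.n_events} events, "
      f"{c_model.iterations} Newton iterations):")
print(c_model.summary_frame().round(3).to_string())

# R-Model: five GTV radiomics features, Box-Cox + z-scaled with federated
# transform constants (per-feature exponent lambda fitted on pooled moments)
features = ["GTV volume", "GTV surface area", "GTV sphericity",
            "GTV intensity mean", "GTV texture entropy"]
transforms = fit_transforms(hub, features, "r_cohort")
print("\nBox-Cox exponents:", {f: transforms[f]["lam"] for f in features})
r_model = cox_fit(hub, features, "r_cohort", transforms=transforms)
print(f"R-Model ({r_model.n} subjects):")
print(r_model.summary_frame().round(3).to_string())

# CR-Model: stations compute the two linear predictors locally (the LP values
# are stored at the node, never transmitted), then a 2-covariate fit combines them
compute_linear_predictor(hub, c_model, "LP_C", "r_cohort")
compute_linear_predictor(hub, r_model, "LP_R", "r_cohort")
cr_model = fit_cr_model(hub, "r_cohort")
print("\nCR-Model over locally stored linear predictors:")
print(cr_model.summary_frame().round(3).to_string())

hci = node_concordance(hub, c_model, "c_cohort")
print("\nPer-node Harrell concordance of the C-Model (0.5 = no discrimination):")
print({n: round(v["hci"], 3) for n, v in sorted(hci.items())})
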