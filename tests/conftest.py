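"""Shared fixtures: the generated five-node consortium (session-scoped, built
once through the full schema-on-read pipeline) and small toy-node helpers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest
import yaml

from fairfed import (
    ConsortiumVocabulary,
    DataStation,
    FederationHub,
    generate_consortium_fixtures,
)

#: The published consortium case-mix table the fixtures reproduce.
#: None means "variable/category absent at that node" (printed as a dash).
TABLE1 = {
    "columns": ["HN1", "HNSCC", "OPC", "HEAD-NECK", "HN3"],
    "Sample size": [137, 492, 606, 298, 165],
    "age_mean": [61.9, 57.8, 60.5, 63.3, 62.6],
    "age_range": [(44, 83), (28, 87), (33, 89), (18, 90), (29, 84)],
    "Sex": {
        "Female": [26, 69, 125, 71, 43],
        "Male": [111, 423, 481, 227, 122],
    },
    "Tumour stage": {
        "T1": [35, 92, 103, 39, 14],
        "T2": [32, 203, 198, 109, 31],
        "T3": [24, 117, 183, 94, 68],
        "T4": [46, 80, 122, 46, 52],
        "Tx": [None, None, None, 10, None],
    },
    "Nodal stage": {
        "N0": [60, 45, 101, 59, 48],
        "N1": [16, 53, 61, 40, 45],
        "N2": [58, 378, 397, 180, 54],
        "N3": [3, 16, 47, 19, 18],
        "Nx": [None, None, None, None, None],
    },
    "Metastasis stage": {
        "M0": [136, 492, 606, 294, 165],
        "M1": [1, 0, None, 0, 0],
        "Mx": [None, None, None, 4, None],
    },
    "Overall stage (7th ed.)": {
        "I": [24, 3, 11, 4, None],
        "II": [11, 16, 38, 27, None],
        "III": [23, 67, 85, 61, None],
        "IV": [79, 406, 472, 204, None],
        "Unspecified": [None, None, None, 2, None],
    },
    "Tumour location": {
        "Nasopharynx": [None, None, None, 28, None],
        "Oropharynx": [88, 492, 606, 203, 63],
        "Hypopharynx": [None, None, None, 13, 31],
        "Larynx": [49, None, None, 45, 64],
        "Unknown": [None, None, None, 9, None],
    },
    "HPV status": {
        "Positive": [23, 248, 356, 78, 34],
        "Negative": [58, 44, 143, 46, 29],
        "Unknown": [56, 200, 107, 174, 102],
    },
    "Radiotherapy type": {
        "Radiotherapy": [100, 57, 309, 48, 104],
        "Chemoradiotherapy": [37, 435, 297, 250, 61],
    },
    "Survival status": {
        "Censored": [63, 376, 347, 242, 77],
        "Deceased": [74, 116, 259, 56, 88],
    },
}

C_COHORT = {"HN1": 88, "HNSCC": 492, "OPC": 606, "HEAD-NECK": 203, "HN3": 63}
R_COHORT = {"HN1": 80, "HNSCC": 396, "OPC": 582, "HEAD-NECK": 203, "HN3": 60}


@pytest.fixture(scope="session")
def vocab() -> ConsortiumVocabulary:
    return ConsortiumVocabulary.load()


@pytest.fixture(scope="session")
def consortium_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("consortium")
    generate_consortium_fixtures(out, seed=42)
    return out


@pytest.fixture(scope="session")
def stations(consortium_dir, vocab) -> dict[str, DataStation]:
    return {
        p.name: DataStation.from_directory(p, vocab) for p in sorted(consortium_dir.iterdir())
    }


@pytest.fixture(scope="session")
def hub(stations) -> FederationHub:
    return FederationHub(stations, k_min=1)


# --------------------------------------------------------------------------
# toy-node helper
# --------------------------------------------------------------------------

def write_node_dir(
    path: Path,
    node_id: str,
    clinical: pd.DataFrame,
    metadata: dict,
    mappings: dict,
) -> Path:
    node = path / node_id
    node.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(node / "clinical.csv", index=False)
    (node / "clinical_metadata.yaml").write_text(yaml.safe_dump(metadata), encoding="utf-8")
    (node / "clinical_mappings.yaml").write_text(yaml.safe_dump(mappings), encoding="utf-8")
    return node


def toy_sex_node(path: Path, node_id: str = "TOY", *, males: int = 3, females: int = 2,
                 sex_col: str = "sex", codes: tuple[str, str] = ("M", "F")) -> Path:
    """A tiny node with an identifier, a sex column and an age column."""
    n = males + females
    frame = pd.DataFrame(
        {
            "pid": [f"{node_id}-{i}" for i in range(n)],
            sex_col: [codes[0]] * males + [codes[1]] * females,
            "age": list(range(50, 50 + n)),
        }
    )
    metadata = {
        "columns": {
            "pid": {"kind": "identifier"},
            sex_col: {"kind": "categorical_nominal"},
            "age": {"kind": "continuous", "unit": "years"},
        }
    }
    mappings = {
        "node_id": node_id,
        "classes": {sex_col: "Sex", "age": "Age in years"},
        "values": {sex_col: {codes[0]: "Male", codes[1]: "Female"}},
        "units": {"age": "Year"},
    }
    return write_node_dir(path, node_id, frame, metadata, mappings)
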