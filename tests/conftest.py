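import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phoenix_score as px
from phoenix_score import scoring

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked_example():
    return px.worked_example_row()


@pytest.fixture(scope="session")
def grid():
    return px.boundary_grid()


def score_grid(frame: pd.DataFrame) -> pd.DataFrame:
    """Score a canonical-column grid with the vectorized package scorers."""
    resp = scoring.score_respiratory(
        frame["pf_ratio"], frame["sf_ratio"], frame["on_imv"],
        frame["on_respiratory_support"],
    )
    cv = scoring.score_cardiovascular(
        frame["vasoactive_count"], frame["lactate_mmol_l"],
        frame["map_mmhg"], frame["age_months"],
    )
    coag = scoring.score_coagulation(
        frame["platelets_k_ul"], frame["inr"], frame["d_dimer_mg_l"],
        frame["fibrinogen_mg_dl"],
    )
    neuro = scoring.score_neurologic(
        frame["gcs"], frame["fixed_pupils_bilateral"]
    )
    endo = scoring.score_endocrine(frame["glucose_mg_dl"])
    immu = scoring.score_immunologic(
        frame["anc_cells_mm3"], frame["alc_cells_mm3"]
    )
    renal = scoring.score_renal(frame["creatinine_mg_dl"], frame["age_months"])
    hep = scoring.score_hepatic(frame["bilirubin_mg_dl"], frame["alt_iu_l"])
    total = resp + cv + coag + neuro
    sepsis = (total >= 2).astype(np.int64)
    return pd.DataFrame(
        {
            "respiratory": resp,
            "cardiovascular": cv,
            "coagulation": coag,
            "neurologic": neuro,
            "endocrine": endo,
            "immunologic": immu,
            "renal": renal,
            "hepatic": hep,
            "total": total,
            "total8": total + endo + immu + renal + hep,
            "sepsis": sepsis,
            "septic_shock": sepsis * (cv >= 1).astype(np.int64),
        }
    )


@pytest.fixture(scope="session")
def grid_scores(grid):
    return score_grid(grid)
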