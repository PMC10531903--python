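import numpy as np
import pandas as pd
import pytest

import episig as ep


@pytest.fixture(scope="session")
def small_manifest():
    """2000-probe manifest + annotation on 3 autosomes plus X/Y."""
    return ep.simulate_manifest(2000, 3, seed=11)


@pytest.fixture(scope="session")
def signal_study(small_manifest):
    """12 cases vs 60-control pool with a 60-probe hypomethylation
    signature at Δβ = −0.10."""
    manifest, annotation = small_manifest
    return ep.simulate_cohort(
        manifest, 12, 75, ep.SignatureSpec(60, -0.10),
        seed=21, annotation=annotation)


@pytest.fixture(scope="session")
def discovery(signal_study):
    """Matched controls, M-values and scored DMP table for signal_study."""
    study = signal_study
    cases = study.case_ids
    sheet = study.samples
    mr = ep.match_controls(sheet[sheet["group"] == "case"],
                           sheet[sheet["group"] == "control_pool"])
    controls = mr.matched_control_ids
    m = ep.beta_to_m(study.beta)
    stats = ep.dmp_statistics(study.beta, m, sheet, cases, controls)
    stats = ep.attach_auc_scores(stats, study.beta, cases, controls)
    return {"study": study, "cases": cases, "controls": controls,
            "m": m, "stats": stats}


def toy_beta(values: np.ndarray, prefix: str = "s") -> pd.DataFrame:
    """probes x samples frame with generated ids."""
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])])
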