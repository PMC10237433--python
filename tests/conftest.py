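import arviz as az
import numpy as np
import pandas as pd
import pytest

from gngbias.inference import FitResult, GoNogoHBA, MCMCConfig
from gngbias.models import get_spec
from gngbias.simulate import default_study_config, generate_study


def make_table(sessions: dict[str, tuple]) -> pd.DataFrame:
    """Build a trial table from {subject: (cues, actions, feedback)}."""
    frames = []
    for sid, (cues, actions, feedback) in sessions.items():
        frames.append(pd.DataFrame({
            "subjID": sid,
            "trial": np.arange(1, len(cues) + 1),
            "cue": cues,
            "keyPressed": actions,
            "outcome": feedback,
        }))
    return pd.concat(frames, ignore_index=True)


def fake_fit(group_draws: dict, subject_draws: dict | None = None,
             subject_ids=("s1", "s2"), variant="M3",
             converged=True) -> FitResult:
    """Assemble a FitResult from hand-specified posterior draws.

    ``group_draws`` maps parameter name -> natural-scale group-mean draws
    (1-D).  ``subject_draws`` maps name -> (draws, subjects) natural-scale
    individual draws (defaults to tiling the group draws).
    """
    spec = get_spec(variant)
    subject_ids = list(subject_ids)
    n = len(next(iter(group_draws.values())))
    posterior, dims = {}, {}
    for p in spec.parameter_names:
        g = np.asarray(group_draws[p], dtype=float)
        posterior[f"group_{p}"] = g[None, :]
        if subject_draws and p in subject_draws:
            sub = np.asarray(subject_draws[p], dtype=float)
        else:
            sub = np.tile(g[:, None], (1, len(subject_ids)))
        posterior[p] = sub[None, :, :]
        dims[p] = ["subject"]
    idata = az.from_dict(posterior=posterior, dims=dims,
                         coords={"subject": subject_ids})
    return FitResult(idata=idata, spec=spec, subject_ids=subject_ids,
                     pointwise_loglik=np.zeros((n, len(subject_ids))),
                     diagnostics={"max_rhat": 1.0, "n_divergent": 0},
                     converged=converged, mcmc=MCMCConfig(), data=None)


@pytest.fixture(scope="session")
def study():
    """Small synthetic two-group study with ground-truth manifest."""
    table_a, table_b, manifest = generate_study(
        default_study_config(seed=2024, n_a=6, n_b=6))
    return table_a, table_b, manifest


@pytest.fixture(scope="session")
def m3_fit(study):
    """One desk-scale Model 3 fit, shared across evaluation/stats tests."""
    table_a, _, _ = study
    est = GoNogoHBA(variant="M3", n_chains=2, n_warmup=500,
                    n_keep_per_chain=500, seed=42)
    est.fit(table_a)
    return est.result_, table_a
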