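"""Model diagnostics: visual predictive check, residuals, Morris screening.

Re-fits the sparse PD dataset from the previous step's generating setup,
runs a Monte-Carlo visual predictive check (10/50/90 percentile bands
with 90% confidence intervals), computes IWRES and NPDE residual series,
and screens the IVPT transport parameters with Morris elementary effects
to rank their influence on 36-h epidermal accumulation.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dermapk import defaults
from dermapk.calibration import morris_screen
from dermapk.core import simulate
from dermapk.ivpt import build_ivpt_system, layer_accumulation
from dermapk.pkpd import fit_population, residual_diagnostics, vpc
from dermapk.synthetic import StudyDesign, gen_pd_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20250903

sys.path.insert(0, str(Path(__file__).resolve().parent))
fit_pd = __import__("05_fit_pd")


def main():
    OUT.mkdir(exist_ok=True)
    design = StudyDesign(pd_n_subjects=6)
    exposures = fit_pd.exposures()
    records, _ = gen_pd_dataset(fit_pd.TRUTH, exposures, design, seed=SEED)
    fit = fit_population(records, fit_pd.TRUTH, seed=SEED, max_iter=400)
    model = fit["model"]

    # VPC on the Differin exposure at the clinical observation times
    t_obs = np.asarray(design.pd_observation_times)
    t_exp, c_exp = exposures["Differin"]
    c_obs = np.interp(t_obs, t_exp, c_exp)
    bands = vpc(model, t_obs, c_obs, n_subjects=6, n_replicates=1000, seed=SEED)
    bands.to_csv(OUT / "pd_vpc.csv", index=False)
    print("VPC percentile bands (endpoint units):")
    print(bands.round(3).to_string(index=False))

    diag = residual_diagnostics(records, model, fit["ebes"], seed=SEED, n_sim=500)
    diag.to_csv(OUT / "pd_diagnostics.csv", index=False)
    print(f"\nIWRES: mean={diag['iwres'].mean():.3f} sd={diag['iwres'].std():.3f}")
    print(f"NPDE:  mean={diag['npde'].mean():.3f} sd={diag['npde'].std():.3f}")

    # Morris screening of IVPT transport parameters
    forms = defaults.example_formulations()
    skin = defaults.default_skin()
    transport = defaults.default_transport()

    def epidermis_at_36h(params):
        tr = transport.with_params(**params)
        res = simulate(build_ivpt_system(forms["Differin"], skin, tr), [0.0, 18.0, 36.0])
        return layer_accumulation(res, skin).epidermis_amount_per_weight[-1]

    ranges = {
        "kp_cp_sc": (30.0, 3000.0),
        "p_cp_sc": (2e-4, 2e-2),
        "kp_sc_ve": (0.005, 0.5),
        "p_sc_ve": (5e-5, 5e-3),
        "kp_ve_dm": (0.05, 5.0),
        "p_dm_rec": (5e-5, 5e-3),
    }
    res = morris_screen(epidermis_at_36h, ranges, n_trajectories=8, seed=SEED)
    table = pd.DataFrame(
        {"parameter": res.parameters, "mu_star": res.mu_star, "sigma": res.sigma}
    ).sort_values("mu_star", ascending=False)
    table.to_csv(OUT / "morris_screening.csv", index=False)
    print("\nMorris screening of 36-h epidermal accumulation (ug/mg per unit range):")
    print(table.round(5).to_string(index=False))
    print(f"\nwrote pd_vpc.csv, pd_diagnostics.csv, morris_screening.csv in {OUT}")


if __name__ == "__main__":
    main()
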