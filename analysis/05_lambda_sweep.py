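"""Sensitivity of the GM-WM CBV difference to the inversion regularisation.

Re-inverts one noisy synthetic dataset with the morphology-enabled
inversion at lambda in {100, 300, 1000, 3000, 5000} and reports the
GM - WM CBV difference per setting (the difference is used because the
global CSF-reference shift cancels in it).  Lower lambda smooths the
maps and compresses the tissue contrast; the difference saturates once
the data term dominates.  -> results/lambda_sweep.csv
"""

from pathlib import Path

from dynqsm.config import AcquisitionParams, InversionConfig, RunConfig
from dynqsm.evaluation import lambda_sweep
from dynqsm.pipeline import reconstruct, simulate_subject

OUT = Path("results")
GRID = [100.0, 300.0, 1000.0, 3000.0, 5000.0]


def main() -> None:
    cfg = RunConfig(grid_shape=(40, 40, 40), phantom_seed=1, noise_seed=2,
                    noise_sd=0.02,
                    acquisition=AcquisitionParams(n_timepoints=50),
                    inversion=InversionConfig(method="tkd"))
    phantom, blood, series = simulate_subject(cfg)
    products = reconstruct(series, phantom.masks, cfg.physio,
                           inversion=cfg.inversion, windows=cfg.windows,
                           phantom=phantom)
    table = lambda_sweep(products, GRID)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "lambda_sweep.csv", index=False)
    print(table.to_string(index=False))
    true_diff = phantom.true_cbv("gm") - phantom.true_cbv("wm")
    print(f"\nphantom-true GM - WM difference: {true_diff:.2f} mL/100 g")


if __name__ == "__main__":
    main()
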