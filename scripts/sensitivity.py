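#!/usr/bin/env python
"""Sensitivity of session outcomes to the interstitial albumin concentration.

The interstitial albumin level is the one patient parameter the baseline
scenario cannot pin down from first principles; this sweep shows how the
conventional-HD and tryptophan-HD session outcomes and the calibrated drug
free half-life move across a plausible range (40-80% of plasma albumin).

Usage:  python scripts/sensitivity.py [--values 240 300 360 420 480]
"""

from __future__ import annotations

import argparse
from dataclasses import replace


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--values", type=float, nargs="+",
                    default=[240.0, 300.0, 360.0, 420.0, 480.0],
                    help="interstitial albumin concentrations to sweep (uM)")
    args = ap.parse_args()

    from pbutkin import (
        Prescription,
        calibrate_displacer,
        initialize_patient,
        simulate_session,
    )
    from pbutkin.config import load_preset

    cfg = load_preset("baseline_tryptophan")
    params0, solutes, rx_trp, dialyzer, tube, numerics = cfg.build()

    print(f"{'alb_is_uM':>9} {'trp_t12_min':>11} "
          f"{'HD_IS_RR':>8} {'HD_IS_rem':>9} {'trp_IS_RR':>9} {'trp_IS_rem':>10} "
          f"{'trp_residual_mg':>15}")
    for alb in args.values:
        params = replace(params0, albumin_is=alb * 1e-6)
        drug = calibrate_displacer(rx_trp.drug, params, solutes,
                                   rx_template=rx_trp, dialyzer=dialyzer,
                                   tube=tube, numerics=numerics)
        patient = initialize_patient(params, solutes)
        hd = simulate_session(patient.copy(), Prescription(modality="hd"),
                              params, solutes, dialyzer, tube, numerics)
        trp = simulate_session(patient.copy(), replace(rx_trp, drug=drug),
                               params, solutes, dialyzer, tube, numerics)
        print(f"{alb:9.0f} {drug.free_half_life:11.2f} "
              f"{hd.outcome.rr_pct[0]:8.1f} {hd.outcome.removal_mg[0]:9.1f} "
              f"{trp.outcome.rr_pct[0]:9.1f} {trp.outcome.removal_mg[0]:10.1f} "
              f"{trp.outcome.drug_residual_mg:15.0f}")


if __name__ == "__main__":
    main()
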