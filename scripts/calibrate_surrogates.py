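"""Verify the frozen default parameters of the demonstration surrogates.

Run from the repository root::

    python scripts/calibrate_surrogates.py

Checks (and prints) the qualitative behaviors the surrogates were frozen
to exhibit:

* negative-feedback oscillator: >= 2 local maxima of the output over the
  default horizon; reducing either inhibitor-production parameter
  (transcription or translation) to 15% raises the output AUC (S > 0);
* cascade: aperiodic nominal response (<= 1 local maximum); reducing the
  transcript degradation rate amplifies the response (S > 0) while
  reducing the phosphorylation rate suppresses it (S < 0).

Exits non-zero if any assertion fails, so the script doubles as a guard
when surrogate defaults are ever revisited.
"""

import sys

from aucsens import SimulationConfig, auc, simulate
from aucsens.demo_models import (
    DEFAULT_HORIZONS,
    count_local_maxima,
    make_cascade,
    make_negative_feedback_oscillator,
)

ALPHA = 0.15


def s_for(model, cfg, param, alpha):
    nominal = simulate(model, model.nominal_params, cfg)
    a_nom = auc(nominal, model.output_variable, cfg.horizon_T)
    altered = dict(model.nominal_params)
    altered[param] *= alpha
    a_alt = auc(simulate(model, altered, cfg), model.output_variable, cfg.horizon_T)
    return a_alt / a_nom - 1.0


def main() -> int:
    ok = True

    osc = make_negative_feedback_oscillator()
    cfg = SimulationConfig(horizon_T=DEFAULT_HORIZONS["negative_feedback"])
    peaks = count_local_maxima(
        simulate(osc, osc.nominal_params, cfg).variable(osc.output_variable), 1e-3
    )
    print(f"oscillator: {peaks} output peaks over T={cfg.horizon_T} (need >= 2)")
    ok &= peaks >= 2
    for param in ("mdm2_transcription", "mdm2_translation"):
        s = s_for(osc, cfg, param, ALPHA)
        print(f"oscillator: S({param}, alpha={ALPHA}) = {s:+.4f} (need > 0)")
        ok &= s > 0

    cas = make_cascade()
    cfg = SimulationConfig(horizon_T=DEFAULT_HORIZONS["cascade"])
    peaks = count_local_maxima(
        simulate(cas, cas.nominal_params, cfg).variable(cas.output_variable)
    )
    print(f"cascade: {peaks} output peaks over T={cfg.horizon_T} (need <= 1)")
    ok &= peaks <= 1
    s = s_for(cas, cfg, "transcript_deg", ALPHA)
    print(f"cascade: S(transcript_deg, alpha={ALPHA}) = {s:+.4f} (need > 0)")
    ok &= s > 0
    s = s_for(cas, cfg, "stat_phos", ALPHA)
    print(f"cascade: S(stat_phos, alpha={ALPHA}) = {s:+.4f} (need < 0)")
    ok &= s < 0

    print("calibration", "OK" if ok else "FAILED")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
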