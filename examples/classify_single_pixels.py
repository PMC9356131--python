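"""Simulate one pixel per staple-crop pattern and classify it.

Prints, per pixel, the detected cropping intensity, the season metrics the
decision rules consume (LSWI_min / RCLE for rice, EVE / EVL for wheat,
RCPN for maize) and the resulting pattern code.
"""

import phenocrop as pc

for code, name in [(15, "single rice"), (16, "single wheat"), (14, "single maize")]:
    series = pc.simulate_pixel(code, purity=1.0, noise_sd=0.01, gap_rate=0.1, seed=3)
    result = pc.classify_pixel(series, fraction=1.0)
    print(f"\ntrue pattern {code} ({name}) -> predicted {result.code}, "
          f"intensity {result.intensity}")
    for window, metrics, label in zip(result.windows, result.metrics, result.labels):
        print(f"  season heading DOY {window.heading_doy}: label={label.value}")
        print(f"    lswi_min={metrics.lswi_min:.3f}  rcle={metrics.rcle:.3f}  "
              f"rcpn={metrics.rcpn:.3f}  "
              + (f"eve={metrics.eve:.3f} evl={metrics.evl:.3f}" if metrics.eve is not None
                 else "eve/evl: outside wheat calendar window"))

print("\nA rice season passes when LSWI_min > 0.1 and RCLE < 0.42 (pure pixels); "
      "wheat needs EVE > 0.32 and EVL > 0.12 near the calendar heading date; "
      "maize needs RCPN > 0.45.")
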