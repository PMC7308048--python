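"""Protein stability statistics from a cycloheximide (CHX) chase.

Densitometry readings (target band over loading control) are normalized to
percent of the t = 0 signal, fitted with a one-phase decay
y(t) = 100 * exp(-K t), and two conditions are compared with the extra
sum-of-squares F test: does the mutant protein decay faster than wild type?
Also shows the reporter and flow-cytometry normalizations.
"""

import numpy as np

from famburden import (
    compare_decay_constants,
    compute_nmfi,
    fit_one_phase_decay,
    normalize_chx,
    normalize_luciferase,
    percent_of_reference,
)

hours = np.array([0.0, 3.0, 6.0, 9.0, 12.0])

# raw band intensities: target and loading control, one blot per condition
wt_target = np.array([2.10, 1.85, 1.66, 1.45, 1.27])
wt_control = np.array([1.00, 1.02, 0.98, 1.01, 0.99])
mut_target = np.array([1.90, 1.31, 0.86, 0.59, 0.42])
mut_control = np.array([0.95, 1.00, 0.97, 1.02, 1.01])

wt = normalize_chx(hours, wt_target, wt_control)
mut = normalize_chx(hours, mut_target, mut_control)

for name, curve in (("WT", wt), ("mutant", mut)):
    fit = fit_one_phase_decay(curve)  # y0 fixed at 100, plateau at 0
    print(f"{name:<7} K = {fit.K:.4f}/h   half-life = {fit.half_life:.2f} h")

res = compare_decay_constants(wt, mut)
print(f"shared-K vs separate-K: F({res.df_num},{res.df_den}) = {res.F:.2f}, "
      f"p = {res.p:.4g}")
print("a small p rejects a shared decay constant: the mutant is degraded "
      "significantly faster.\n")

# dual-luciferase reporter: firefly normalized per-well by Renilla, then
# scaled so the unstimulated control condition averages 1 (fold activation)
firefly = np.array([210.0, 198.0, 840.0, 805.0, 610.0, 588.0])
renilla = np.array([105.0, 99.0, 102.0, 98.0, 101.0, 97.0])
conditions = ["ctrl", "ctrl", "wt", "wt", "mut", "mut"]
folds = normalize_luciferase(firefly, renilla, conditions, "ctrl")
for cond in ("wt", "mut"):
    mean = np.mean([f for f, c in zip(folds, conditions) if c == cond])
    print(f"reporter fold activation, {cond}: {mean:.2f}")

# flow cytometry surface expression: nMFI = MFI(sample)/MFI(control)
wt_nmfi = compute_nmfi(4200.0, 1000.0)
mut_nmfi = compute_nmfi(2650.0, 1000.0)
print(f"surface expression: mutant nMFI {mut_nmfi:.2f} = "
      f"{percent_of_reference(mut_nmfi, wt_nmfi):.0f}% of WT")
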