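"""Spoiled-gradient signal model: forward curve, inversion, VFA calibration.

Builds a noiseless variable-flip-angle (VFA) series for lung tissue
(T1 = 800 ms) at the UTE protocol settings (TR = 3.7 ms, flips 5/8/16/25
degrees), then recovers the scanner scale constant A and the tissue
relaxation rate R1 from that series alone.
"""

import numpy as np

import lungquant as lq

params = lq.AcquisitionParams()
A_true, t1_true = 1000.0, 800.0

print("flip angle -> signal (A = 1000, T1 = 800 ms, TR = 3.7 ms):")
signals = []
for alpha in params.flip_angles_deg:
    s = lq.ute_signal(A_true, alpha, params.tr_ms, t1_true)
    signals.append(s)
    print(f"  {alpha:>4.0f} deg : S = {s:7.3f}")
print("The signal is not monotone in flip angle: it peaks at the Ernst angle.")

calib = lq.fit_pre_calibration(signals, params)
print(f"\nVFA fit: A = {calib.A:.3f}, R1_pre = {calib.r1_pre:.4f} 1/s "
      f"(T1 = {calib.t1_pre_ms:.1f} ms), residual = {calib.fit_residual:.2e}")
print("Noiseless recovery is exact: this pair (A, R1_pre) calibrates the "
      "single-flip-angle inversion used after contrast arrives.")

# a post-contrast voxel: 1.794 mM of Gd3+ at relaxivity 3 /mM/s shortens
# T1 from 2000 ms to 170 ms
r1_post = 1000.0 / 2000.0 + 3.0 * 1.794
s_post = lq.ute_signal(A_true, 25.0, params.tr_ms, 1000.0 / r1_post)
t1_back = lq.invert_signal_to_T1(s_post, calib.A, 25.0, params.tr_ms)
print(f"\npost-contrast voxel: S(25 deg) = {s_post:.2f} -> T1 = {t1_back:.1f} ms "
      f"-> C = {(1000.0 / t1_back - 0.5) / 3.0:.3f} mM")
print("Closing the loop: signal -> T1 -> concentration via the relaxivity relation.")
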