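"""Score one synthetic MWR exam: Q_max, asymmetry coefficients, R, class.

A high-risk exam is drawn (hot internal focus on the left breast), scored,
and classified against the published thresholds Q_max > 2.0 °C and
R > 2.5 °C.
"""

from mwrisk import HIGH_RISK, generate_thermogram, score_thermogram

tg = generate_thermogram(HIGH_RISK, seed=7, patient_id="demo")
s = score_thermogram(tg)

print(f"exam {tg.patient_id}:")
print(f"  T_max internal {s.t_max_mw:.1f} °C, mean {s.t_mean_mw:.1f} °C")
print(f"  T_max skin     {s.t_max_ir:.1f} °C, mean {s.t_mean_ir:.1f} °C")
print(f"  Q_max = {s.q_max:.2f} °C   (focal heating; threshold 2.0)")
print(f"  k_int = {s.k_int:.2f} °C at point {s.n_int}; "
      f"k_skin = {s.k_skin:.2f} °C at point {s.n_skin}")
print(f"  R     = {s.r:.2f} °C   ({s.branch.value} branch; threshold 2.5)")
print(f"  class: {s.mwr_class.value}")
# Q_max measures how far the hottest breast point rises above the gland
# average; R measures left/right asymmetry. Both above threshold -> the
# screening rule suspects malignancy.
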