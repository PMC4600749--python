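"""Simulate an endosome acidifying against an internalized nanobuffer load.

A 0.5-um organelle pumping 288 H+/s acidifies from pH 7.4; 30 micelles
(64,000 amines each, apparent pKa 5.3) absorb the pumped protons while
their cooperative protonation window is titrated, clamping the lumen near
pH 5.3.  The plateau statistics and the OFF-ON activation half-time are
reported against a load-free control.
"""

from nanobuffer import (
    NanobufferLoad,
    OrganelleModel,
    activation_signal,
    plateau_stats,
    simulate_lumen,
)

model = OrganelleModel()  # 6.5e-17 L, 288 H+/s, 40 mM/pH intrinsic buffer
load = NanobufferLoad(micelles_per_organelle=30, pKa=5.3)

control = simulate_lumen(model, NanobufferLoad(0, pKa=5.3), duration=30_000, dt=10)
traj = simulate_lumen(model, load, duration=30_000, dt=10)
report = plateau_stats(traj, load, control)

print(f"control reaches pH {control.pH[-1]:.2f} with no dwell at any set point")
print(f"loaded organelle: plateau detected = {report.detected}")
print(f"  plateau mean pH   : {report.plateau_mean_pH:.3f}  (load pKa 5.300)")
print(f"  plateau duration  : {report.plateau_duration/60:.0f} min")
print(f"  activation delay  : {report.activation_delay/60:.0f} min vs control")

signal, t50 = activation_signal(traj)
print(f"OFF-ON reporter half-activation t50: {t50/60:.0f} min")
print("The clamp lasts ~ micelles x amines x 0.8 / pump_rate: proton bookkeeping.")
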