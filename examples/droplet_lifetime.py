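"""How long can a small water droplet stay airborne before it evaporates?

Evaluates the Stokes sedimentation and evaporation timescales for a 100 μm
radius droplet falling 5 m through air at 20 °C / 50% relative humidity,
then solves for the radius where the two timescales cross.
"""

from prepolymer import DropletParams, droplet_volume, optimal_radius
from prepolymer.droplet import summarize

params = DropletParams(r=100.0, H=5.0)
res = summarize(params)
r_star, t_cross = optimal_radius(params)

print(f"terminal velocity      : {res.v_t:.3f} m/s")
print(f"fall time from {params.H:.0f} m    : {res.t_fall:.2f} s")
print(f"evaporation lifetime   : {res.t_life:.1f} s")
print(f"droplet volume         : {res.volume:.4f} uL")
print(f"optimal radius         : {r_star:.1f} um (lives {t_cross:.1f} s)")
print()
print("Below the optimal radius a droplet dries out before reaching the")
print("ground; above it, it lands first. Droplets near this size have the")
print("longest airborne life while still drying -- the regime in which")
print("dissolved nucleotides get concentrated into a supersaturated drop.")
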