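"""Phasor FLIM-FRET: from photon-count decay images to FRET efficiency.

Simulates a time-correlated photon-counting image with a donor-only region
and a donor+acceptor region, writes/reads nothing (all in memory), and runs
the fit-free phasor pipeline: per-pixel Fourier transform, density-map
Gaussian cluster fit, lifetime and efficiency.
"""

from clcassay.flim_phasor import fret_efficiency, phasor_transform, roi_lifetime
from clcassay.synthdata import FlimSpec, simulate_flim

TAU_D = 2.22   # ns, unquenched donor
TAU_DA = 1.89  # ns, donor next to an acceptor

spec = FlimSpec(
    image_shape=(40, 50),
    n_bins=256,
    rep_rate_mhz=80.0,
    tau_map={"donor_only": TAU_D, "donor_acceptor": TAU_DA},
    photons_per_pixel=10_000.0,
    seed=2,
)
stack = simulate_flim(spec)

for roi in ("donor_only", "donor_acceptor"):
    _, _, _, pooled = phasor_transform(stack, roi)
    cluster, tau = roi_lifetime(stack, roi)
    print(
        f"{roi:>16}: pooled phasor (G={pooled.g:.3f}, S={pooled.s:.3f}), "
        f"cluster centroid ({cluster.centroid_g:.3f}, {cluster.centroid_s:.3f}), "
        f"tau = {tau:.3f} ns"
    )

_, tau_d = roi_lifetime(stack, "donor_only")
_, tau_da = roi_lifetime(stack, "donor_acceptor")
res = fret_efficiency(tau_d, tau_da)
print(f"\nFRET efficiency E = 1 - tau_DA/tau_D = {res.efficiency:.3f}")
print(
    "\nBoth clusters sit on the universal semicircle (monoexponential"
    "\ndecays); the quenched donor's shorter lifetime moves its cluster"
    "\nclockwise, and E quantifies the quenching - evidence that the two"
    "\ntagged subunits assemble into one heteromeric complex."
)
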