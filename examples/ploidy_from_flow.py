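"""Call ploidy from flow-cytometry fluorescence and date a WGD event.

Simulates haploid/diploid control strains plus one evolving line whose
genome doubles mid-experiment, calibrates fluorescence-per-genome from
the controls, calls ploidy at each timepoint and reports the first
tetraploid observation.
"""

from wgdkit.flowploidy import calibrate, call_ploidy, detect_wgd
from wgdkit.simulate import simulate_fluorescence_sample

controls = [
    (simulate_fluorescence_sample(1.0, 5000, 0.6, 0.05, seed=1), 1.0),
    (simulate_fluorescence_sample(2.0, 5000, 0.6, 0.05, seed=2), 2.0),
]
cal = calibrate(controls)
print(f"calibration: {cal.unit:.1f} fluorescence units per haploid genome")

# a line observed at four generation timepoints, doubling before gen 385
trajectory = []
for gen, ploidy in [(0, 2.0), (90, 2.0), (385, 4.0), (770, 4.0)]:
    sample = simulate_fluorescence_sample(
        ploidy, 5000, 0.6, 0.05, seed=100 + gen, line_id="M1_07", timepoint=gen
    )
    call = call_ploidy(sample, cal)
    trajectory.append(call)
    print(
        f"gen {gen:>4}: G1 peak {call.g1_peak:7.1f} -> "
        f"{call.ploidy_continuous:.2f}n (class {call.ploidy_class})"
    )

event = detect_wgd(trajectory, baseline_ploidy=2)
print(
    f"WGD first observed at generation {event.first_tetraploid_timepoint}; "
    f"reverted={event.reverted}"
)
# The G1 peak position divided by the calibration unit is the genome
# copy number; the doubling between gen 90 and 385 is the WGD.
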