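"""The core Criticality Analysis pipeline on synthetic tabular data.

Generates a 3-class Gaussian-blob table (classes ordered by overall
magnitude, like the Iris species), clamps each row onto a 4-oscillator
RCC-controlled Berry network, and summarises each sample's settled orbit
by the maxima of the network's total F and M signals.  A 5-NN classifier
on those two numbers shows how much class structure the nonlinear
representation preserves -- without any training of the representation.
"""

import criticality as ca

ds = ca.make_blobs(n_classes=3, n_per_class=40, n_features=4,
                   separation=6.0, seed=1)
spec = ca.NetworkSpec(model="berry", n_oscillators=4, weights=0.0005,
                      input_map=(0, 1, 2, 3))
schedule = ca.ClampSchedule(steps_per_sample=10_000, step_size=0.1,
                            transient_fraction=0.5)
result = ca.represent(ds, spec, schedule, input_scalars=[0.0075] * 4,
                      shuffle_seed=1)

table = result.table
print(table.head(6).to_string(index=False))
print("...")
print("\nper-class means of the representation:")
print(table.groupby("label")[["max_F", "max_M"]].mean().round(2))

report = ca.grouping_report(table, table["label"], ["max_F", "max_M"],
                            n_neighbors=5, seed=0)
print(f"\n5-NN accuracy on (max_F, max_M): {report['knn_accuracy']:.3f}")
print(f"between/within separability ratio: {report['separability_ratio']:.2f}")
print("Accuracy near 1 means nearby samples landed on nearby orbits: the "
      "2-D orbit summary preserved the 4-D class neighbourhoods.")
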