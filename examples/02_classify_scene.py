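"""Maximum-likelihood classification of a synthetic six-class scene.

Generates a 120×120 scene from the default spectral library, trains on 40
random truth points per class and reports the hold-out error matrix,
accuracies and Cohen's kappa.
"""

import lulcst as L

specs = L.default_class_specs()
truth = L.generate_truth_map((120, 120), specs, seed=1)
scene = L.generate_scene(truth, specs, seed=2)

train = L.sample_truth_points(truth, 40, seed=3)
test = L.sample_truth_points(truth, 40, seed=4)

sigs = L.extract_signatures(scene.optical_bands, train,
                            class_names=truth.class_names)
lulc = L.classify_mlc(scene.optical_bands, sigs,
                      class_names=truth.class_names)

em = L.build_error_matrix(lulc, test)
print("error matrix (rows = predicted, columns = reference):")
print(em.to_dataframe())
print()
print(L.accuracy_table(em).round(2).to_string(index=False))
print("\nOverall accuracy is the share of held-out truth points the map "
      "got right; kappa discounts the agreement expected by chance. With "
      "well-separated class signatures both sit near their ceilings "
      "(100% / 1.0).")
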