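"""Accuracy assessment of a crop map from a ground-survey confusion matrix.

Feeds the published national ground-survey confusion matrix (18,379 sites,
2015-2021; rows are map estimates, columns reference data) through the
accuracy machinery and prints the full report.
"""

import numpy as np

from phenocrop.validation import accuracy_metrics

matrix = np.array(
    [
        [5929, 45, 56, 357],
        [78, 2220, 139, 220],
        [205, 90, 4216, 151],
        [366, 85, 212, 4010],
    ]
)
report = accuracy_metrics(matrix, ("rice", "wheat", "maize", "others"))

print(report.to_frame().to_string())
print(f"\nUser accuracy (%): "
      + "  ".join(f"{c}={report.ua[c]:.2f}" for c in report.classes))
print(f"Overall accuracy (%): {100 * report.oa:.2f}")
print(f"Kappa: {report.kappa:.2f}")
print("\nProducer accuracy conditions on the map class (row), user accuracy "
      "on the reference class (column); kappa corrects agreement for chance.")
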