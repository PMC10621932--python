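"""Registry of the classifier families used by the wrapper and harness.

Model fitting is delegated to scikit-learn; this module only fixes the
naming, the seeds, and the few non-default settings.  "dnn" follows the
common small-tabular practice of a two-hidden-layer perceptron (64/32
units with early stopping) rather than a deep convolutional model.
"""

from __future__ import annotations

from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


def _builders(seed: int):
    return {
        "svm": lambda: SVC(kernel="linear", C=1.0, random_state=seed),
        "nb": lambda: GaussianNB(),
        "dt": lambda: DecisionTreeClassifier(random_state=seed),
        "rf": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "1nn": lambda: KNeighborsClassifier(n_neighbors=1),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(64, 32),
            early_stopping=True,
            max_iter=500,
            random_state=seed,
        ),
    }


ALIASES = {"dnn": "mlp", "k-nn": "knn", "naive_bayes": "nb"}

SUPPORTED = ("svm", "nb", "dt", "rf", "knn", "mlp", "1nn")


def make_classifier(name, seed: int = 0):
    """Build a fresh, seeded estimator from its short name.

    An already-constructed estimator is cloned, so callers may pass their
    own configured model anywhere a name is accepted.
    """
    if not isinstance(name, str):
        return clone(name)
    key = ALIASES.get(name.lower(), name.lower())
    builders = _builders(seed)
    if key not in builders:
        raise ValueError(
            f"unknown classifier {name!r}; supported: {', '.join(SUPPORTED)}"
        )
    return builders[key]()
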