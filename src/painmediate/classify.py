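"""Leave-one-subject-out forced-choice classification of cue effect maps.

Each subject contributes a pair of contrast images — one for the social
cue effect and one for the conditioned-cue effect — restricted to an
analysis mask.  A linear support vector machine trained on all other
subjects' labeled pairs scores the held-out pair; the subject counts as
correct iff the social image receives the higher social-side decision
value than its CS image (forced choice, which is invariant to any
monotone transform of the decision values).  Significance of the
accuracy comes from an exact two-sided binomial test against chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC

__all__ = ["ClassificationResult", "loso_forced_choice"]


@dataclass
class ClassificationResult:
    accuracy: float
    se: float
    p: float
    correct: np.ndarray
    n_subjects: int

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "se": self.se, "p": self.p,
                "n_subjects": self.n_subjects,
                "correct": self.correct.astype(int).tolist()}


def loso_forced_choice(
    social: np.ndarray,
    cs: np.ndarray,
    C: float = 1.0,
    standardize: bool = True,
) -> ClassificationResult:
    """LOSO forced-choice separation of Social vs CS contrast images.

    ``social`` and ``cs`` are (n_subjects, n_features) pattern matrices
    on a common mask.  Feature standardization uses training-fold
    statistics only, so no held-out information enters training.
    """
    social = np.atleast_2d(np.asarray(social, float))
    cs = np.atleast_2d(np.asarray(cs, float))
    if social.shape != cs.shape:
        raise ValueError("social and cs pattern sets must match in shape")
    n = social.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if social.std() == 0 or cs.std() == 0:
        raise ValueError("constant images cannot be classified")

    correct = np.zeros(n, bool)
    for held in range(n):
        train_idx = np.delete(np.arange(n), held)
        X = np.vstack([social[train_idx], cs[train_idx]])
        y = np.r_[np.ones(n - 1), -np.ones(n - 1)]
        if standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
            test = (np.vstack([social[held], cs[held]]) - mu) / sd
        else:
            test = np.vstack([social[held], cs[held]])
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, y)
        dec = clf.decision_function(test)
        correct[held] = dec[0] > dec[1]

    k = int(correct.sum())
    acc = k / n
    se = float(np.sqrt(acc * (1 - acc) / n))
    p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    return ClassificationResult(acc, se, p, correct, n)
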