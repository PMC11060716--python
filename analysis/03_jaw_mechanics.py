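"""Jaw functional indices, ordination/classification, quadrate sensitivity.

Generates jaw landmark sets per diet class with systematic differences
in lever geometry and robusticity, computes the functional indices
(AMA, PMA, OMA, AO, relative max/mean height), ordinates them (PCA),
classifies a fossil-like jaw by FDA posteriors, and runs the
quadrate-placement sensitivity analysis on it.
"""

import pathlib

import numpy as np
import pandas as pd

from trophotax.comparative import fda_fit_predict, pca_transform
from trophotax.jaws import JawLandmarks, compute_jaw_indices, quadrate_sensitivity

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 31

# per-diet lever geometry: (adductor height, adductor setback from joint,
# retroarticular extension, jaw depth).  Force-adapted feeders get taller,
# more posteriorly-set adductors and deeper jaws.
DIET_GEOMETRY = {
    "Folivore": (2.6, 0.4, 1.2, 1.9),
    "GranivoreH": (3.0, 0.3, 0.6, 2.3),
    "GranivoreS": (2.2, 0.4, 0.7, 1.7),
    "Generalist": (1.8, 0.6, 0.7, 1.4),
    "Invertivore": (1.4, 0.8, 0.6, 1.0),
    "Piscivore": (1.1, 1.0, 0.5, 0.8),
}
N_PER_DIET = 12


def make_jaw(rng, adductor_h, setback, retro, depth):
    length = rng.uniform(8, 14)
    scale = length / 10.0
    jitter = lambda s: rng.normal(0, s)
    return JawLandmarks(
        jaw_joint=(length, 0.4 * scale),
        anterior_tip=(0.0, 0.0),
        posterior_tooth=(0.45 * length + jitter(0.2), 0.15 * scale),
        closing_muscle_attachment=(
            length - setback * scale + jitter(0.1),
            adductor_h * scale + jitter(0.15),
        ),
        opening_muscle_attachment=(length + retro * scale + jitter(0.08), 0.3 * scale),
        tooth_row_line=((0.0, 0.0), (0.45 * length, 0.0)),
        outline_heights=np.clip(
            depth * scale * np.sin(np.linspace(0.15, np.pi - 0.15, 100))
            + rng.normal(0, 0.05 * scale, 100),
            0.05,
            None,
        ),
        jaw_length_axis=((0.0, 0.0), (length, 0.0)),
        side="lower",
    )


def main():
    ROOT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows, labels = [], []
    for diet, geom in DIET_GEOMETRY.items():
        for i in range(N_PER_DIET):
            idx = compute_jaw_indices(make_jaw(rng, *geom)).as_series()
            idx.name = f"{diet}_{i}"
            rows.append(idx)
            labels.append(diet)
    X = pd.DataFrame(rows)
    labels = pd.Series(labels, index=X.index)
    X.to_csv(ROOT / "jaw_indices.csv")

    pca = pca_transform(X, standardize=True)
    print("PCA variance explained (%):", np.round(pca.variance_explained_pct[:3], 1))
    pca.scores.iloc[:, :3].assign(diet=labels).to_csv(ROOT / "jaw_pca_scores.csv")

    # a fossil-like jaw: folivore-grade levers, generalist-grade depth
    fossil = make_jaw(np.random.default_rng(SEED + 1), 2.5, 0.45, 1.1, 1.5)
    fx = compute_jaw_indices(fossil).as_series().to_frame().T
    fx.index = ["fossil_taxon"]
    model, pred = fda_fit_predict(X, labels, X_new=fx)
    post = pred.posterior.iloc[0].sort_values(ascending=False)
    print("FDA training misclassification:", round(model.train_misclassification, 3))
    print("fossil posterior (top 3):")
    print(post.head(3).to_string(float_format="%.3f"))
    pred.posterior.to_csv(ROOT / "jaw_fda_posteriors.csv")

    shifts = np.round(np.linspace(-0.05, 0.05, 11), 3)
    sens = quadrate_sensitivity(fossil, shifts)
    sens.to_csv(ROOT / "quadrate_sensitivity.csv")
    ama = sens["AMA"]
    print(
        f"quadrate shift -5%..+5% of jaw length: AMA {ama.iloc[0]:.3f} -> "
        f"{ama.loc[0.0]:.3f} -> {ama.iloc[-1]:.3f} "
        "(anterior shifts raise closing MA)"
    )


if __name__ == "__main__":
    main()
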