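"""Train the bundled default reliability model on a synthetic cohort.

Regenerates src/cnqc/data/default_model.json from scratch. The cohort is
30 samples per group (A, B, C, flat, highDLRS) at the default simulation
conditions, features extracted with K=120 and CBS at alpha=0.01 with 500
permutations.
"""
import os
import sys

from cnqc.cbs import CBSConfig
from cnqc.classifier import TrainingSet, train_model
from cnqc.features import extract_features
from cnqc.simulate import SimProfileSpec, simulate_cohort
from cnqc.stepfit import StepFitConfig

COHORT_SEED = 20
N_PER_GROUP = 30


def main(out_path=None):
    if out_path is None:
        out_path = os.path.join(
            os.path.dirname(__file__), "..", "src", "cnqc", "data", "default_model.json"
        )
    cohort = simulate_cohort(N_PER_GROUP, spec=SimProfileSpec(seed=COHORT_SEED))
    fvs, labels = [], []
    for s in cohort:
        fv = extract_features(
            s.profile,
            StepFitConfig(K=120),
            CBSConfig(alpha=0.01, n_permutations=500, rng_seed=s.seed),
        )
        fvs.append(fv)
        labels.append(s.label)
    model = train_model(TrainingSet(fvs, labels))
    model.save(out_path)
    print(f"trained on {len(labels)} samples -> {out_path}")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else None)
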