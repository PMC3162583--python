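import numpy as np
import pandas as pd
import pytest

from ginipipe import famtau, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profiles(n_families, n_features, seed=0, shift=0.0, n_up=0, sizes=None):
    """RankedProfileSet straight from the miRNA generator (or custom family sizes)."""
    if sizes is None:
        design = simulate.StudyDesign(n_families=n_families, seed=seed)
        cfg = simulate.MirnaSimConfig(
            n_mirnas=n_features, n_up=n_up, n_down=0, shift=shift,
            family_sd=0.5, noise_sd=0.3,
        )
        expr, truth = simulate.simulate_mirna_matrix(design, cfg)
        meta = expr.sample_meta.copy()
        meta["is_patient"] = meta["status"] == "affected"
        return famtau.RankedProfileSet(values=expr.values, sample_meta=meta), truth
    # custom (n_patients, n_healthy) per family with plain iid values
    rng = np.random.default_rng(seed)
    cols, fam_ids, flags = {}, [], []
    for f, (np_, nh) in enumerate(sizes):
        for p in range(np_):
            cols[f"F{f}-P{p}"] = rng.normal(size=n_features)
            fam_ids.append(f"F{f}")
            flags.append(True)
        for h in range(nh):
            cols[f"F{f}-H{h}"] = rng.normal(size=n_features)
            fam_ids.append(f"F{f}")
            flags.append(False)
    values = pd.DataFrame(cols, index=[f"m{i}" for i in range(n_features)])
    meta = pd.DataFrame(
        {"family_id": fam_ids, "is_patient": flags}, index=list(cols)
    )
    return famtau.RankedProfileSet(values=values, sample_meta=meta), None
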