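"""Built-in reference community model and synthetic pilot-data fixtures.

The reference model is a hand-specified :class:`CommunityModel` (synthetic;
not fitted to any real survey) with parameters typical of a 16S ASV
case-control study:

* log2 mean abundance: 3 Gaussian components — a large low-abundance mode,
  a mid-abundance mode and a small high-abundance tail;
* log2 fold change | abundance: 2 components — a dominant near-null bulk
  whose spread shrinks slightly with abundance, plus a minority "affected"
  component with larger, abundance-correlated effects;
* dispersion trend d(m) = 0.3 * (0.2 + 5 / m): asymptotic dispersion 0.2
  with a strong low-abundance excess, scaled by the standard 0.3 factor.
"""

from __future__ import annotations

import numpy as np

from .community import CommunityModel, DispersionTrendModel
from .mixtures import ConditionalLfcMixture, GaussianMixtureModel
from .simulate import SimulatedDataset, simulate_community


def default_community_model() -> CommunityModel:
    """The built-in synthetic reference model used by fixtures and demos."""
    mm = GaussianMixtureModel()
    mm.weights_ = np.array([0.5, 0.3, 0.2])
    mm.means_ = np.array([2.5, 5.5, 8.5])
    mm.sds_ = np.array([1.0, 1.0, 1.2])
    mm.n_components_ = 3
    mm.selection_ = []

    lm = ConditionalLfcMixture()
    lm.weights_ = np.array([0.75, 0.25])
    lm.lambda_ = np.log(lm.weights_ / lm.weights_[0])
    lm.mean_coefs_ = np.array([[0.0, 0.0], [0.5, 0.15]])
    lm.logsd_coefs_ = np.array([[-0.5, -0.05], [0.3, 0.0]])
    lm.variance_form_ = "linear"
    lm.n_components_ = 2

    dt = DispersionTrendModel(scale=0.3)
    dt.c0_, dt.c1_ = 0.2, 5.0

    model = CommunityModel(mm, lm, dt, log_base=2.0, meta={"source": "built-in synthetic"})
    model.validate()
    return model


def make_fixture(
    n_taxa: int = 500, n_per_group: int = 50, seed: int | None = 0
) -> SimulatedDataset:
    """Synthetic pilot dataset with known ground truth from the reference model."""
    return simulate_community(
        default_community_model(), n_taxa, n_per_group, n_per_group, seed=seed
    )
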