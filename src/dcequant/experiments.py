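"""Reusable study-level experiments on the synthetic cohort.

These wrap the pipeline stages into the specific analyses reported by the
package: the replicated cohort AUC of Ktrans percent change for response
prediction, and the four-condition Ktrans comparison.
"""

from __future__ import annotations

import numpy as np

from .pkfit import fit_tm, roi_average_curve
from .pipeline import FIXED_R10
from .protocol import AcquisitionProtocol
from .stats import percent_change, roc_auc
from .synthetic import CohortDesign, default_aif, generate_truth_maps, \
    simulate_dce_series

__all__ = ["cohort_ktrans_auc", "auc_replicates"]


def cohort_ktrans_auc(seed: int, n_per_group: int = 8, n_voxels: int = 60,
                      grid_shape=(8, 8, 6), noise_sigma: float = 0.02,
                      change_visit: str = "V3",
                      protocol: AcquisitionProtocol | None = None) -> float:
    """ROC AUC of ROI-based Tofts Ktrans percent change for pCR prediction.

    Simulates one cohort (``n_per_group`` patients per response group at V1
    and ``change_visit``), fits the ROI-average curve of each patient-visit
    with the Tofts model at fixed R1,0, and returns the logistic-ROC AUC of
    the percent change.
    """
    protocol = protocol or AcquisitionProtocol()
    design = CohortDesign(n_pcr=n_per_group, n_nonpcr=n_per_group,
                          visits=("V1", change_visit), n_voxels=n_voxels,
                          grid_shape=grid_shape, noise_sigma=noise_sigma,
                          seed=int(seed))
    aif = default_aif(protocol)
    labels, changes = [], []
    for p in range(design.n_patients):
        values = {}
        for visit in design.visits:
            sub = int(np.random.SeedSequence(
                [design.seed, 19, p, 0 if visit == "V1" else 1]
            ).generate_state(1)[0] % (2**31))
            truth = generate_truth_maps(design, p, visit)
            dce = simulate_dce_series(truth, protocol, aif,
                                      noise_sigma=noise_sigma, seed=sub)
            curve = roi_average_curve(dce, truth.roi_mask)
            values[visit] = fit_tm(curve, FIXED_R10, aif, protocol).ktrans
        labels.append(1 if design.group_of(p) == "pCR" else 0)
        changes.append(percent_change(values[change_visit], values["V1"]))
    return roc_auc(np.array(labels), np.array(changes)).auc


def auc_replicates(n_reps: int, base_seed: int, **kwargs) -> np.ndarray:
    """AUCs of ``n_reps`` independently seeded cohort replicates."""
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(base_seed).spawn(n_reps)]
    return np.array([cohort_ktrans_auc(s, **kwargs) for s in seeds])
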