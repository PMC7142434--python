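"""Reference treatment profiles for cooked Spanish mackerel muscle.

Pool relaxation parameters (T21/T22/T23 apex times in ms and per-gram peak
areas A21/A22/A23) and texture-profile statistics (mean +/- SD over
replicate specimens) for raw muscle and the four classical cooking
treatments.  These numbers parameterize the synthetic cohort generator:
each treatment group is drawn around its profile, so downstream parameter
recovery can be checked against known ground truth.
"""

from __future__ import annotations

import numpy as np

from fishnmr.synthetic import TreatmentProfile

TEXTURE_PARAMETERS = (
    "hardness",
    "resilience",
    "springiness",
    "chewiness",
    "gumminess",
    "adhesiveness",
)

#: Pool parameters per treatment: (T2 means ms, T2 SDs, per-gram areas, area SDs).
_POOLS = {
    "control": ((1.01, 51.04, 429.96), (0.05, 1.99, 42.12),
                (526.50, 9577.17, 180.82), (102.29, 682.30, 57.56)),
    "boiling": ((0.85, 30.21, 533.10), (0.08, 1.56, 56.36),
                (341.55, 5667.80, 546.17), (15.43, 281.15, 227.15)),
    "steaming": ((0.77, 26.60, 275.61), (0.09, 0.46, 14.37),
                 (307.60, 5261.56, 843.55), (15.74, 198.75, 117.85)),
    "roasting": ((0.66, 18.01, 228.71), (0.13, 1.57, 20.67),
                 (355.09, 4162.73, 299.38), (42.90, 891.11, 126.77)),
    "frying": ((1.44, 17.43, 142.94), (0.43, 2.50, 16.45),
               (470.28, 1707.53, 1113.33), (100.14, 399.69, 235.26)),
}

#: Texture statistics per treatment, ordered as TEXTURE_PARAMETERS.
_TEXTURE = {
    "control": ((177.01, 0.23, 0.76, 87.6, 115.78, 0.65),
                (11.50, 0.02, 0.03, 9.76, 10.28, 0.02)),
    "boiling": ((1040.98, 0.24, 0.79, 493.22, 624.36, 0.60),
                (120.72, 0.03, 0.03, 84.62, 94.01, 0.03)),
    "steaming": ((996.51, 0.22, 0.80, 459.91, 576.04, 0.58),
                 (128.69, 0.01, 0.03, 70.94, 81.92, 0.03)),
    "roasting": ((2399.01, 0.30, 0.87, 1430.15, 1643.56, 0.68),
                 (222.93, 0.04, 0.02, 235.32, 263.85, 0.07)),
    "frying": ((6561.44, 0.25, 0.85, 3255.96, 3826.61, 0.59),
               (623.91, 0.04, 0.05, 464.38, 349.78, 0.07)),
}

TREATMENT_PROFILES: dict[str, TreatmentProfile] = {
    name: TreatmentProfile(
        name=name,
        pool_t2_means=np.asarray(_POOLS[name][0], dtype=float),
        pool_t2_sds=np.asarray(_POOLS[name][1], dtype=float),
        pool_area_means=np.asarray(_POOLS[name][2], dtype=float),
        pool_area_sds=np.asarray(_POOLS[name][3], dtype=float),
        texture_means=np.asarray(_TEXTURE[name][0], dtype=float),
        texture_sds=np.asarray(_TEXTURE[name][1], dtype=float),
    )
    for name in _POOLS
}


def pool_feature_vector(profile: TreatmentProfile) -> np.ndarray:
    """Per-gram pool feature vector [A21, A22, A23, ln T21, ln T22, ln T23]."""
    return np.concatenate(
        [profile.pool_area_means, np.log(profile.pool_t2_means)]
    )


#: Per-feature allowance in the weighted minimum-norm linkage fit.  The
#: bound-water features (A21, ln T21) are down-weighted: a CPMG train whose
#: first echo falls at 0.4 ms barely determines them, so the linkage should
#: not lean on them.
_LINKAGE_ALLOWANCE = np.array([0.1, 1.0, 1.0, 0.1, 1.0, 1.0])


def linkage_coefficients() -> np.ndarray:
    """Global linear map from pool features to the six texture parameters.

    Fitted once by weighted minimum-norm least squares so that every
    treatment group's mean pool features reproduce its mean texture
    profile exactly (five groups, seven unknowns per response: six
    features plus an intercept; the two spare degrees of freedom are spent
    by the weighting, which keeps the load off the poorly determined
    bound-water features).  Returns an array of shape (6, 7); the last
    column is the intercept.  Deterministic, so the coefficients are a
    fixed package constant in all but storage.
    """
    profiles = [TREATMENT_PROFILES[n] for n in _POOLS]
    features = np.stack([pool_feature_vector(p) for p in profiles])
    targets = np.stack([p.texture_means for p in profiles])
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    design = np.hstack(
        [(features - mu) / sd * _LINKAGE_ALLOWANCE, np.ones((len(profiles), 1))]
    )
    w = np.linalg.pinv(design) @ targets  # (7, 6), minimum weighted norm
    coeffs = np.zeros((6, 7))
    coeffs[:, :6] = (w[:6] * (_LINKAGE_ALLOWANCE / sd)[:, None]).T
    coeffs[:, 6] = w[6] - coeffs[:, :6] @ mu
    return coeffs


#: Cap on the texture dispersion the pool-driven mode may inject, as a
#: fraction of each group's reference texture SD.  Replicate-level
#: decay-texture coupling is not identifiable from group-level summary
#: tables, so the generator keeps it subordinate to repeatability noise.
_RESPONSE_CAP = 0.05


def _texture_gains() -> np.ndarray:
    """Global texture gains on (A22, A23), shape (6, 2).

    Direction: least-squares regression of the group mean textures on the
    group mean immobilized/free-water areas (the two pool quantities a
    linear calibration on whole decays tracks globally).  Magnitude:
    scaled so that no treatment group's propagated texture SD exceeds
    ``_RESPONSE_CAP`` times its reference texture SD.
    """
    profiles = [TREATMENT_PROFILES[n] for n in _POOLS]
    areas = np.stack(
        [[p.pool_area_means[1], p.pool_area_means[2], 1.0] for p in profiles]
    )
    targets = np.stack([p.texture_means for p in profiles])
    w, *_ = np.linalg.lstsq(areas, targets, rcond=None)
    gains = w[:2].T  # (6 textures, 2 areas)
    area_sds = np.stack(
        [[p.pool_area_sds[1], p.pool_area_sds[2]] for p in profiles]
    )
    ref_sds = np.stack([p.texture_sds for p in profiles])
    response = np.abs(np.einsum("tf,gf->gt", gains, area_sds))
    inflation = (response / np.maximum(ref_sds, 1e-300)).max(axis=0)
    scale = np.minimum(_RESPONSE_CAP / np.maximum(inflation, 1e-300), 1.0)
    return gains * scale[:, None]


def local_linkage(profile: TreatmentProfile) -> np.ndarray:
    """Local (per-treatment) affine pool->texture map, shape (6, 7).

    The generator's view of the pool->texture law: the law is smooth and
    nonlinear across cooking treatments, so each group gets its local
    linearization — the exact group mean texture as operating point plus
    the fixed global gains on the immobilized (A22) and free (A23) water
    areas.  Feature order matches ``pool_feature_vector``; the last column
    is the intercept.
    """
    gains = _texture_gains()
    coeffs = np.zeros((6, 7))
    coeffs[:, 1] = gains[:, 0]
    coeffs[:, 2] = gains[:, 1]
    coeffs[:, 6] = profile.texture_means - coeffs[:, :6] @ pool_feature_vector(profile)
    return coeffs
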