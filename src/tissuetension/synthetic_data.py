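"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the measurements of a magnetic-tensiometry study of
breast-tumour spheroids across an EMT panel: side-view images of flattened
aggregates, AFM cell-cell detachment curves, shrinking scratch-wound masks
and per-field transwell invasion counts.  Default condition parameters are
anchored to the published panel (a no-targeting CRISPR control "NT", two
NME1-ablated clones, two NME2-ablated clones, and normal-like MCF10A
cells): surface tensions of 16 +/- 9, 4 +/- 3, 7 +/- 2, 16 +/- 5,
13 +/- 5 and 45 +/- 18 mN/m respectively, detachment forces of
1.8 +/- 0.8, 1.4 +/- 0.5, 1.2 +/- 0.4, 2.0 +/- 1.0 and 1.9 +/- 0.8 nN,
a ~6.5-fold invasion increase for NME1 loss, and 24 h wound coverages of
~75% (NME1-ablated) vs ~55% (others).

Geometry defaults: initial spheroid radius 450 +/- 70 um, field gradient
170 T/m, field 530 mT.  The per-volume magnetization M_V is an input of
the real instrument (measured by magnetometry); the synthetic default of
1000 A/m is chosen so that control-like tensions give clearly flattened
but well-conditioned shapes (dimensionless capillary constant of order 1).

Every generator takes an explicit seed and is bit-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage

from .assay_quant import InvasionCounts, WoundSeries
from .force_curve import ForceCurve
from .laplace_shape import GeometryObservables, ShapeParams, integrate_profile
from .profile_extraction import SideViewImage, extract_geometry
from .tension_fit import MagneticContext, fit_tension
from .tension_fit import _solve_b_for_volume

#: Condition panel: (gamma mean, gamma sd) mN/m; (detachment mean, sd) nN;
#: invasion fold over control; wound coverage targets at 24 h and 48 h.
DEFAULT_CONDITIONS: dict[str, dict] = {
    "NT": dict(gamma=(16.0, 9.0), detachment=(1.8, 0.8), invasion_fold=1.0, wound=(0.55, 0.90)),
    "NME1#A": dict(gamma=(4.0, 3.0), detachment=(1.4, 0.5), invasion_fold=6.5, wound=(0.78, 1.00)),
    "NME1#B": dict(gamma=(7.0, 2.0), detachment=(1.2, 0.4), invasion_fold=6.5, wound=(0.78, 1.00)),
    "NME2#A": dict(gamma=(16.0, 5.0), detachment=(2.0, 1.0), invasion_fold=1.0, wound=(0.55, 0.90)),
    "NME2#B": dict(gamma=(13.0, 5.0), detachment=(1.9, 0.8), invasion_fold=1.0, wound=(0.55, 0.90)),
    "MCF10A": dict(gamma=(45.0, 18.0), detachment=(2.5, 0.8), invasion_fold=1.0, wound=(0.55, 0.90)),
}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a full synthetic study.

    Defaults are the published panel values; the magnetic context and the
    sample sizes mirror the experimental design (9-15 aggregates and ~45
    AFM curves per condition, 5 invasion fields x 3 replicates).
    """

    conditions: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITIONS.items()})
    control: str = "NT"
    r0_um: float = 450.0
    r0_sd_um: float = 70.0
    m_v_a_per_m: float = 1000.0
    grad_b_t_per_m: float = 170.0
    b_field_mt: float = 530.0
    scale_um_per_px: float = 1.0
    blur_sigma_px: float = 1.5
    image_noise: float = 0.03
    n_aggregates: int = 10
    n_afm_curves: int = 45
    afm_noise_sd_nn: float = 0.1
    n_wound_fields: int = 10
    n_wound_replicates: int = 3
    invasion_control_mean: float = 20.0
    n_invasion_fields: int = 5
    n_invasion_replicates: int = 3
    seed: int = 0

    @property
    def magnetic_context(self) -> MagneticContext:
        return MagneticContext(m_v=self.m_v_a_per_m, grad_b=self.grad_b_t_per_m, b_field_mt=self.b_field_mt)


def capillary_constant_um2(gamma_mn_per_m: float, ctx: MagneticContext) -> float:
    """c = M_V grad(B) / gamma, converted to 1/um^2."""
    if gamma_mn_per_m <= 0:
        raise ValueError("gamma must be positive")
    c_si = ctx.force_density / (gamma_mn_per_m * 1e-3)  # 1/m^2
    return c_si * 1e-12


def true_shape(gamma_mn_per_m: float, ctx: MagneticContext, r0_um: float) -> tuple[ShapeParams, GeometryObservables]:
    """Equilibrium shape of an incompressible aggregate of initial radius R0.

    The capillary constant follows from gamma and the magnetic calibration;
    the apex curvature is solved so the flattened volume equals the initial
    sphere volume 4 pi R0^3 / 3.
    """
    c_um = capillary_constant_um2(gamma_mn_per_m, ctx)
    c_t = c_um * r0_um**2
    b_t = _solve_b_for_volume(c_t)
    prof = integrate_profile(ShapeParams(b_t, c_t))
    obs = GeometryObservables(
        h=float(prof.z[-1]) * r0_um, w=2.0 * prof.x_max * r0_um, V=prof.volume * r0_um**3
    )
    return ShapeParams(b=b_t / r0_um, c=c_um), obs


def synth_aggregate_image(
    gamma_mn_per_m: float,
    ctx: MagneticContext,
    r0_um: float = 450.0,
    scale_um_per_px: float = 1.0,
    blur_sigma_px: float = 1.5,
    noise: float = 0.03,
    margin_px: int = 25,
    seed: int = 0,
) -> tuple[SideViewImage, dict]:
    """Render a side-view image of a flattened aggregate of known tension.

    Returns the image and a ground-truth record with the generating
    (b, c, h, w, V, gamma).  The record carries ``sphere_like=True`` when
    the flattening h - w is below one pixel, i.e. gamma is too large to be
    measurable at this magnification.
    """
    rng = np.random.default_rng(seed)
    params, obs = true_shape(gamma_mn_per_m, ctx, r0_um)
    prof = integrate_profile(ShapeParams(params.b * r0_um, params.c * r0_um**2))
    z_um = prof.z * r0_um
    x_um = prof.x * r0_um

    s = scale_um_per_px
    n_rows = int(np.ceil(obs.h / s)) + 2 * margin_px
    n_cols = int(np.ceil(obs.w / s)) + 2 * margin_px
    axis_col = n_cols / 2.0
    rows = np.arange(n_rows)
    # depth of each pixel-row centre below the apex; apex at the top margin
    z_centers = (rows - margin_px + 0.5) * s
    half_w = np.full(n_rows, -1.0)  # rows outside the drop match no column
    inside = (z_centers >= 0) & (z_centers <= obs.h)
    half_w[inside] = np.interp(z_centers[inside], z_um, x_um)
    cols = np.arange(n_cols)
    dist = np.abs((cols[None, :] - axis_col + 0.5) * s)
    mask = dist <= half_w[:, None]

    img = np.where(mask, 0.15, 0.9)
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = {
        "gamma_mn_per_m": gamma_mn_per_m,
        "b_per_um": params.b,
        "c_per_um2": params.c,
        "h_um": obs.h,
        "w_um": obs.w,
        "v_um3": obs.V,
        "r0_um": r0_um,
        "sphere_like": bool(obs.w - obs.h < s),
    }
    return SideViewImage(pixels=img, scale=s), truth


def synth_force_curve(
    dip_nn: float = 1.8,
    noise_sd_nn: float = 0.1,
    drift_nn_per_s: float = 0.0,
    offset_nn: float = 0.0,
    contact_force_nn: float = 5.0,
    dt_s: float = 0.005,
    retract_duration_s: float = 2.0,
    seed: int = 0,
) -> ForceCurve:
    """Synthetic cell-cell force curve with a known adhesion dip.

    Approach ramps to the contact force, a short dwell holds it, retract
    drops through a sharp adhesive minimum of depth ``dip_nn`` (the
    jump-off) and returns to baseline.  Offset, linear drift and Gaussian
    noise are added on top.
    """
    rng = np.random.default_rng(seed)
    n_app, n_dwell = 200, 200
    n_ret = int(round(retract_duration_s / dt_s))
    t_app = np.arange(n_app) * dt_s
    f_app = np.linspace(0.0, contact_force_nn, n_app)
    t_dwell = t_app[-1] + dt_s + np.arange(n_dwell) * dt_s
    f_dwell = np.full(n_dwell, contact_force_nn)
    t_ret = t_dwell[-1] + dt_s + np.arange(n_ret) * dt_s
    u = np.arange(n_ret) / n_ret
    f_ret = np.zeros(n_ret)
    drop = u < 0.10  # pull towards the adhesive minimum
    f_ret[drop] = contact_force_nn - (contact_force_nn + dip_nn) * (u[drop] / 0.10)
    recov = (u >= 0.10) & (u < 0.12)  # sharp jump-off back to baseline
    f_ret[recov] = -dip_nn * (1.0 - (u[recov] - 0.10) / 0.02)

    time = np.concatenate([t_app, t_dwell, t_ret])
    force = np.concatenate([f_app, f_dwell, f_ret])
    force = force + offset_nn + drift_nn_per_s * time + rng.normal(0.0, noise_sd_nn, force.size)
    height = np.concatenate(
        [np.linspace(10.0, 0.0, n_app), np.zeros(n_dwell), 5.0 * (t_ret - t_ret[0])]
    )
    segment = np.array(["approach"] * n_app + ["dwell"] * n_dwell + ["retract"] * n_ret)
    return ForceCurve(time=time, height=height, force=force, segment=segment)


def synth_wound_series(
    coverage_targets: dict[float, float] | float,
    shape_px: tuple[int, int] = (200, 300),
    wound_halfwidth_px: int = 75,
    edge_noise_px: float = 2.0,
    field_id: str = "field0",
    seed: int = 0,
    return_masks: bool = False,
):
    """Shrinking rectangular scratch-wound masks at the stated closure rate.

    ``coverage_targets`` is either a mapping time (h) -> target coverage
    fraction, or a scalar closure fraction per 24 h (sampled at 0/24/48 h).
    The wound is a vertical band that narrows symmetrically; per-row edge
    jitter adds realistic raggedness.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(coverage_targets):
        rate = float(coverage_targets)
        coverage_targets = {0.0: 0.0, 24.0: min(1.0, rate), 48.0: min(1.0, 2 * rate)}
    targets = dict(sorted(coverage_targets.items()))
    if 0.0 not in targets:
        targets = {0.0: 0.0, **targets}
    n_rows, n_cols = shape_px
    center = n_cols / 2.0
    masks, times = [], []
    for t, cov in targets.items():
        hw = wound_halfwidth_px * (1.0 - np.clip(cov, 0.0, 1.0))
        jitter = rng.normal(0.0, edge_noise_px, n_rows) if hw > 0 else np.zeros(n_rows)
        hw_rows = np.clip(hw + jitter, 0.0, n_cols / 2.0) if hw > 0 else np.zeros(n_rows)
        cols = np.arange(n_cols)
        mask = np.abs(cols[None, :] - center + 0.5) < hw_rows[:, None]
        masks.append(mask)
        times.append(t)
    series = WoundSeries.from_masks(times, masks, field_id=field_id)
    return (series, masks) if return_masks else series


def synth_invasion_counts(
    mean_per_field: float,
    n_fields: int = 5,
    n_replicates: int = 3,
    condition: str = "cond",
    seed: int = 0,
) -> InvasionCounts:
    """Poisson per-field invading-cell counts across biological replicates."""
    rng = np.random.default_rng(seed)
    counts = {
        f"rep{r + 1}": [int(v) for v in rng.poisson(mean_per_field, n_fields)]
        for r in range(n_replicates)
    }
    return InvasionCounts(condition=condition, counts=counts)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    while np.any(out <= low):
        bad = out <= low
        out[bad] = rng.normal(mean, sd, bad.sum())
    return out


@dataclass
class StudyDataset:
    """Everything one synthetic study produced, with ground truth."""

    config: StudyConfig
    tension: dict[str, list[dict]]  # per condition: truth + extracted + fit
    afm: dict[str, list[ForceCurve]]
    afm_truth: dict[str, np.ndarray]
    wound: dict[str, list[WoundSeries]]
    invasion: dict[str, InvasionCounts]

    def gamma_fitted(self) -> dict[str, np.ndarray]:
        out = {}
        for cond, recs in self.tension.items():
            vals = [r["fit"].gamma for r in recs if r["fit"].gamma is not None]
            out[cond] = np.asarray(vals)
        return out

    def gamma_true(self) -> dict[str, np.ndarray]:
        return {c: np.asarray([r["truth"]["gamma_mn_per_m"] for r in recs]) for c, recs in self.tension.items()}


def synth_study(config: StudyConfig | None = None, keep_images: bool = False) -> StudyDataset:
    """Generate and analyse a full synthetic study.

    For each condition: draw per-aggregate tensions and initial radii,
    render side-view images, run extraction and the tension fit; generate
    AFM curves at the condition's detachment force, wound series at its
    closure rate, and Poisson invasion counts.  All stochastic draws derive
    from ``config.seed``.
    """
    cfg = config or StudyConfig()
    ctx = cfg.magnetic_context
    root = np.random.default_rng(cfg.seed)

    tension: dict[str, list[dict]] = {}
    afm: dict[str, list[ForceCurve]] = {}
    afm_truth: dict[str, np.ndarray] = {}
    wound: dict[str, list[WoundSeries]] = {}
    invasion: dict[str, InvasionCounts] = {}

    for cond, pars in cfg.conditions.items():
        rng = np.random.default_rng(root.integers(2**31))
        g_mean, g_sd = pars["gamma"]
        gammas = _truncated_normal(rng, g_mean, g_sd, 0.5, cfg.n_aggregates)
        radii = _truncated_normal(rng, cfg.r0_um, cfg.r0_sd_um, 100.0, cfg.n_aggregates)
        recs = []
        for gamma_i, r_i in zip(gammas, radii):
            img, truth = synth_aggregate_image(
                gamma_i,
                ctx,
                r0_um=float(r_i),
                scale_um_per_px=cfg.scale_um_per_px,
                blur_sigma_px=cfg.blur_sigma_px,
                noise=cfg.image_noise,
                seed=int(rng.integers(2**31)),
            )
            obs, contour = extract_geometry(img)
            fit = fit_tension(obs, ctx)
            rec = {"truth": truth, "observed": obs, "fit": fit}
            if keep_images:
                rec["image"] = img
            recs.append(rec)
        tension[cond] = recs

        d_mean, d_sd = pars["detachment"]
        dips = _truncated_normal(rng, d_mean, d_sd, 0.2, cfg.n_afm_curves)
        afm[cond] = [
            synth_force_curve(
                dip_nn=float(d),
                noise_sd_nn=cfg.afm_noise_sd_nn,
                drift_nn_per_s=float(rng.normal(0, 0.002)),
                offset_nn=float(rng.normal(0, 0.2)),
                seed=int(rng.integers(2**31)),
            )
            for d in dips
        ]
        afm_truth[cond] = dips

        cov24, cov48 = pars["wound"]
        wound[cond] = [
            synth_wound_series(
                {0.0: 0.0, 24.0: min(1.0, cov24 + rng.normal(0, 0.03)), 48.0: min(1.0, cov48 + rng.normal(0, 0.02))},
                field_id=f"{cond}-f{i}",
                seed=int(rng.integers(2**31)),
            )
            for i in range(cfg.n_wound_fields * cfg.n_wound_replicates)
        ]

        invasion[cond] = synth_invasion_counts(
            cfg.invasion_control_mean * pars["invasion_fold"],
            n_fields=cfg.n_invasion_fields,
            n_replicates=cfg.n_invasion_replicates,
            condition=cond,
            seed=int(rng.integers(2**31)),
        )

    return StudyDataset(cfg, tension, afm, afm_truth, wound, invasion)
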