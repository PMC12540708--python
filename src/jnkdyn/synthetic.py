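"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (i) scaled expression time courses from the signalling model
itself with known decay rates (and optionally promoter affinity and
delay) plus clipped additive noise, emulating per-condition RNA profiles
at {0, 2, 4, 6, 8} h; (ii) single-cell KTR traces at 10-min frames with a
pre-treatment baseline, programmed pulse structure borrowed from the
model's own active-JNK trajectory, responder/non-responder mixtures and
multiplicative noise; (iii) differential-expression tables with factorial
pass/fail structure over the four significance criteria; and (iv) a
three-archetype profile matrix for clustering benchmarks.  Every generator
is bit-reproducible given its seed and returns the generating truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .clustering import PROFILE_TIMES
from .fitting import _production_rows, _upstream_cached, _grid_indices, _minmax_rows
from .model import ModelParameters, integrate_target, make_stimulus, simulate
from .traces import CellTrace, DEFAULT_FRAME_INTERVAL

__all__ = [
    "SyntheticTruth",
    "gen_expression_profiles",
    "gen_cell_traces",
    "gen_deg_table",
    "gen_archetype_profiles",
]


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic object, enough to regenerate it."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    per_object: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


#: Programmed pulse count per stimulus pattern (responders).
PATTERN_PULSES = {"sustained": 1, "transient": 1, "pulsed": 2, "none": 0}


def gen_expression_profiles(
    condition: str,
    alpha_m_values,
    variant: str = "mass_action",
    noise_sd: float = 0.0,
    seed: int = 0,
    params: ModelParameters | None = None,
    K: float = 0.5,
    n_target: float = 1.8,
    tau: float = 0.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Scaled expression profiles generated from the model with known α_m.

    One gene per entry of ``alpha_m_values``: the model target gene is
    simulated under the condition's stimulus, sampled at {0, 2, 4, 6, 8} h,
    min–max scaled, and perturbed with additive Gaussian noise clipped to
    [0, 1].  ``K``/``n_target`` apply to Hill variants, ``tau`` to delay
    variants.
    """
    alphas = np.atleast_1d(np.asarray(alpha_m_values, dtype=float))
    if np.any(alphas <= 0) or np.any(alphas > 2):
        raise ValueError("alpha_m values must lie in (0, 2]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    p = (ModelParameters() if params is None else params).with_(
        K=K, n_target=n_target
    )
    kind = "hill" if variant.startswith("hill") else "mass_action"
    t, pj, dp = _upstream_cached(p, condition, 8.0, 1e-3)
    if variant.endswith("_delay") and tau > 0:
        pj = np.interp(t - tau, t, pj, left=pj[0])
        dp = np.interp(t - tau, t, dp, left=0.0)
    P, dP = _production_rows(pj, dp, p, kind, n_target, np.array([K]))
    tp_idx = _grid_indices(t, np.asarray(PROFILE_TIMES))
    g0 = (p.beta_t / alphas)[:, None]
    G = integrate_target(t, P, dP, alphas, g0, out_indices=tp_idx)
    scaled = _minmax_rows(G)[:, 0, :]
    rng = np.random.default_rng(seed)
    noisy = np.clip(scaled + rng.normal(0.0, noise_sd, scaled.shape), 0.0, 1.0)
    genes = [f"g{i:04d}" for i in range(alphas.size)]
    frame = pd.DataFrame(noisy, index=pd.Index(genes, name="gene_id"),
                         columns=list(PROFILE_TIMES))
    truth = SyntheticTruth(
        generator="gen_expression_profiles",
        seed=seed,
        params={
            "condition": condition,
            "variant": variant,
            "noise_sd": noise_sd,
            "K": K,
            "n_target": n_target,
            "tau": tau,
        },
        per_object={g: {"alpha_m": float(a)} for g, a in zip(genes, alphas)},
    )
    return frame, truth


def _jnk_bump(pattern: str, frame_times: np.ndarray, shape: str) -> np.ndarray:
    """Unit-height activation profile on the post-treatment frames."""
    stim = make_stimulus(pattern)
    if pattern == "none":
        return np.zeros_like(frame_times)
    if shape == "model":
        t_end = float(frame_times[-1])
        traj = simulate(ModelParameters(), stim, t_end=t_end, dt_out=0.05)
        jnk = traj.species("active_JNK")
        out = np.interp(frame_times, traj.times, jnk, left=0.0)
        return out / out.max()
    if shape == "sigmoid":
        out = np.zeros_like(frame_times)
        for start, end in stim.on_intervals:
            end = min(end, frame_times[-1] + 1.0)
            rise = 1.0 / (1.0 + np.exp(-(frame_times - start - 0.15) / 0.05))
            fall = np.where(
                frame_times <= end, 1.0, np.exp(-(frame_times - end) / 0.25)
            )
            out = np.maximum(out, rise * fall)
        return out
    raise ValueError(f"shape must be 'model' or 'sigmoid', got {shape!r}")


def gen_cell_traces(
    pattern: str,
    n_cells: int = 100,
    responder_fraction: float = 0.9,
    peak_height_mult: float = 2.5,
    noise_sd: float = 0.05,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    pre_frames: int = 4,
    t_end: float = 8.5,
    seed: int = 0,
    shape: str = "model",
) -> tuple[list[CellTrace], SyntheticTruth]:
    """Synthetic single-cell KTR traces with programmed pulse structure.

    Responders follow the model's own active-JNK time course under the
    pattern's stimulus rescaled to C/N units (baseline 1.0, peak
    ``peak_height_mult`` × baseline); non-responders stay at baseline.
    Multiplicative Gaussian noise of relative sd ``noise_sd`` is applied
    per frame.  ``shape='sigmoid'`` swaps in a cheap double-sigmoid bump.
    """
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must lie in [0, 1]")
    if peak_height_mult <= 1.0:
        raise ValueError("peak_height_mult must exceed 1 (baseline units)")
    if pattern not in PATTERN_PULSES:
        raise ValueError(f"pattern must be one of {sorted(PATTERN_PULSES)}")
    rng = np.random.default_rng(seed)
    n_post = int(round(t_end / frame_interval))
    frame_times = (np.arange(-pre_frames, n_post + 1)) * frame_interval
    post = frame_times[frame_times >= 0.0]
    bump = _jnk_bump(pattern, post, shape)
    responders = rng.random(n_cells) < responder_fraction
    traces, per_cell = [], {}
    for i in range(n_cells):
        cell = f"cell{i:04d}"
        clean = np.ones_like(frame_times)
        n_p = 0
        if responders[i]:
            clean[frame_times >= 0.0] += (peak_height_mult - 1.0) * bump
            n_p = PATTERN_PULSES[pattern]
        noise = 1.0 + rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 1.0
        values = np.maximum(clean * noise, 1e-6)
        traces.append(
            CellTrace(cell, frame_times.copy(), values, n_baseline_frames=pre_frames)
        )
        per_cell[cell] = {"responder": bool(responders[i]), "n_pulses": n_p}
    truth = SyntheticTruth(
        generator="gen_cell_traces",
        seed=seed,
        params={
            "pattern": pattern,
            "responder_fraction": responder_fraction,
            "peak_height_mult": peak_height_mult,
            "noise_sd": noise_sd,
            "frame_interval": frame_interval,
            "pre_frames": pre_frames,
            "t_end": t_end,
            "shape": shape,
        },
        per_object=per_cell,
    )
    return traces, truth


def gen_deg_table(
    n_genes: int,
    pass_fractions: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 1.0),
    seed: int = 0,
    condition: str = "sustained",
) -> tuple[pd.DataFrame, set[str]]:
    """DEG-like table with Bernoulli pass/fail per significance criterion.

    ``pass_fractions`` are the independent pass probabilities for the FDR,
    fold-change, max-group-mean and biotype criteria; the expected
    filtered set (genes passing all four) is returned alongside.
    """
    for f in pass_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("pass fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    f_fdr, f_fc, f_mgm, f_bio = pass_fractions
    genes = [f"g{i:04d}" for i in range(n_genes)]
    pass_fdr = rng.random(n_genes) < f_fdr
    pass_fc = rng.random(n_genes) < f_fc
    pass_mgm = rng.random(n_genes) < f_mgm
    pass_bio = rng.random(n_genes) < f_bio

    fdr = np.where(pass_fdr, rng.uniform(1e-4, 0.049, n_genes),
                   rng.uniform(0.051, 0.5, n_genes))
    mgm = np.where(pass_mgm, rng.uniform(1.5, 50.0, n_genes),
                   rng.uniform(0.01, 0.9, n_genes))
    fc = rng.uniform(-0.9, 0.9, (n_genes, 4))
    hit_tp = rng.integers(0, 4, n_genes)
    sign = rng.choice([-1.0, 1.0], n_genes)
    big = sign * rng.uniform(1.1, 4.0, n_genes)
    fc[np.arange(n_genes), hit_tp] = np.where(pass_fc, big,
                                              fc[np.arange(n_genes), hit_tp])
    biotype = np.where(pass_bio, "protein_coding", "lncRNA")

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "condition": condition,
            "biotype": biotype,
            "log2fc_2h": fc[:, 0],
            "log2fc_4h": fc[:, 1],
            "log2fc_6h": fc[:, 2],
            "log2fc_8h": fc[:, 3],
            "fdr": fdr,
            "max_group_mean": mgm,
        }
    )
    expected = {
        g
        for g, a, b, c, d in zip(genes, pass_fdr, pass_fc, pass_mgm, pass_bio)
        if a and b and c and d
    }
    return table, expected


ARCHETYPES = {
    "sustained_like": np.array([0.0, 0.7, 0.9, 1.0, 1.0]),
    "transient_like": np.array([0.0, 1.0, 0.55, 0.25, 0.1]),
    "flat": np.zeros(5),
}


def gen_archetype_profiles(
    n_per_archetype: int = 50,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Three well-separated profile archetypes for clustering benchmarks.

    Sustained-like (late plateau), transient-like (early peak) and flat
    profiles, ``n_per_archetype`` genes each, with clipped additive noise.
    Returns the matrix and the true archetype labels.
    """
    rng = np.random.default_rng(seed)
    rows, labels, genes = [], [], []
    for name, proto in ARCHETYPES.items():
        for i in range(n_per_archetype):
            rows.append(np.clip(proto + rng.normal(0.0, noise_sd, proto.size), 0, 1))
            labels.append(name)
            genes.append(f"{name}_{i:03d}")
    matrix = pd.DataFrame(np.vstack(rows), index=pd.Index(genes, name="gene_id"),
                          columns=list(PROFILE_TIMES))
    return matrix, pd.Series(labels, index=matrix.index, name="archetype")
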