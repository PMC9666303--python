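"""Selectivity, E/I imbalance, weight statistics and phase diagrams."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import PlasticityConfig, Rule
from .fixedpoint import (
    SingularStimulusError,
    critical_inhibition_lower,
    critical_inhibition_upper,
    wd_fixed_points_2d,
)
from .stimuli import StimulusEnsemble, make_pair2d


def selectivity(responses) -> float:
    """Selectivity s = max_k y_k / sum_l y_l of a response profile.

    Ranges from 1/K (all patterns drive the neuron equally) to 1
    (winner-take-all).  Negative responses, which a linear neuron can
    produce transiently, are clipped to zero first since the index
    presumes firing rates.  All-zero responses leave s undefined (NaN,
    with a warning).
    """
    y = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    total = y.sum()
    if total == 0:
        warnings.warn("selectivity undefined for all-zero responses", stacklevel=2)
        return float("nan")
    return float(y.max() / total)


def imbalance(w, u: float, ensemble: StimulusEnsemble | np.ndarray) -> float:
    """Excitation/inhibition imbalance m = (max_k E_k - I) / max_k E_k.

    E_k = sum_i v_i x_i^(k) is the excitatory current for stimulus k
    (v = w + u), and I = u sum_i x_i^(k) the inhibitory current, which
    is stimulus-independent for circulant ensembles; for general
    ensembles I is taken at the pattern maximising E.  m = 1 when the
    neuron is driven by excitation alone (u = 0) and approaches 0 when
    inhibition cancels nearly all excitation.
    """
    X = ensemble.patterns if isinstance(ensemble, StimulusEnsemble) else np.asarray(ensemble)
    w = np.asarray(w, dtype=float)
    E = X @ (w + u)
    I = u * X.sum(axis=1)
    kmax = int(np.argmax(E))
    if E[kmax] == 0:
        warnings.warn("imbalance undefined: no excitatory drive", stacklevel=2)
        return float("nan")
    return float((E[kmax] - I[kmax]) / E[kmax])


@dataclass
class WeightHistogram:
    counts: np.ndarray
    bin_edges: np.ndarray
    skewness: float
    std: float
    mean: float


def weight_histogram(w_samples) -> WeightHistogram:
    """Histogram plus skewness/spread summary of pooled weight samples.

    Bins follow the Freedman-Diaconis rule; skewness is the adjusted
    (bias-corrected) Fisher-Pearson sample skewness.  Intended for the
    qualitative comparison of weight distributions between rules.
    """
    w = np.asarray(w_samples, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("empty weight sample")
    counts, edges = np.histogram(w, bins="fd")
    return WeightHistogram(
        counts=counts,
        bin_edges=edges,
        skewness=float(stats.skew(w, bias=False)) if w.size > 2 else 0.0,
        std=float(w.std(ddof=1)) if w.size > 1 else 0.0,
        mean=float(w.mean()),
    )


@dataclass
class PhaseDiagram:
    """Selectivity and regime of the stable fixed point over (u, phi).

    ``regime`` entries: "standard_wta" (u above u*, winner-take-all,
    s = 1), "weight_dependent_partial" (u** < u < u*, selectivity set by
    inhibition), "pinned_unselective" (u at or below u**, s = 1/2).
    Masked (NaN) entries mark singular stimuli or failed root searches.
    """

    u_values: np.ndarray
    phi_values: np.ndarray
    selectivity: np.ndarray
    regime: np.ndarray
    u_star: np.ndarray
    u_star_star: np.ndarray

    def save(self, path_prefix: str) -> None:
        """Write the selectivity grid as TSV and boundaries as JSON."""
        import json
        from pathlib import Path

        np.savetxt(f"{path_prefix}_selectivity.tsv", self.selectivity, delimiter="\t")
        Path(f"{path_prefix}_boundaries.json").write_text(
            json.dumps(
                {
                    "phi": self.phi_values.tolist(),
                    "u": self.u_values.tolist(),
                    "u_star": self.u_star.tolist(),
                    "u_star_star": self.u_star_star.tolist(),
                },
                indent=1,
            )
        )


def phase_diagram(
    phi_values,
    u_values,
    cfg: PlasticityConfig | None = None,
) -> PhaseDiagram:
    """Map the stable-fixed-point selectivity over (phi, u).

    For each stimulus angle phi the critical levels u*(phi) and
    u**(phi) split the u axis into three regimes; inside the
    weight-dependent band the partial-selectivity fixed point is located
    by the determinant-line root search and its (rectified) responses
    give s.  Rows index phi, columns index u.
    """
    phi_values = np.asarray(phi_values, dtype=float)
    u_values = np.asarray(u_values, dtype=float)
    S = np.full((phi_values.size, u_values.size), np.nan)
    regime = np.full(S.shape, "", dtype=object)
    u_star = np.full(phi_values.size, np.nan)
    u_ss = np.full(phi_values.size, np.nan)
    for i, phi in enumerate(phi_values):
        try:
            ens = make_pair2d(phi)
            u_ss[i] = critical_inhibition_lower(ens)
            u_star[i] = float(np.max(critical_inhibition_upper(ens)))
        except (SingularStimulusError, ValueError):
            # parallel stimuli (phi = pi/4): winner-take-all points do
            # not exist; the row is masked but u** is still recorded
            regime[i, :] = "singular"
            continue
        for j, u in enumerate(u_values):
            if u >= u_star[i]:
                S[i, j] = 1.0
                regime[i, j] = "standard_wta"
            elif u <= u_ss[i]:
                S[i, j] = 0.5
                regime[i, j] = "pinned_unselective"
            else:
                wd_cfg = PlasticityConfig(
                    rule=Rule.WEIGHT_DEPENDENT,
                    u=float(u),
                    tau_w=(cfg.tau_w if cfg else 200.0),
                    tau_theta=(cfg.tau_theta if cfg else 20.0),
                )
                fps = [fp for fp in wd_fixed_points_2d(ens, wd_cfg) if fp.stable]
                if fps:
                    S[i, j] = selectivity(fps[0].responses)
                    regime[i, j] = "weight_dependent_partial"
                else:
                    regime[i, j] = "unresolved"
    return PhaseDiagram(
        u_values=u_values,
        phi_values=phi_values,
        selectivity=S,
        regime=regime,
        u_star=u_star,
        u_star_star=u_ss,
    )
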