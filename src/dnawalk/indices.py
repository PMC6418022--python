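"""Evolutionary indices combining scaling exponents, Chargaff ratio and
entropy into three scalars per sequence.

With α′ = 2 − α and β′ = 2 − β the fractal dimensions of the rescaled-range
and DFA walks, the indices are (natural logarithms throughout):

    v1 = H · ln( α′_RY · ξ · ln(α′_KM) )
    v2 = ln( β′_RY · ln(β′_KM) )
    v3 = ln( β′_SW · ln(α′_SW) )

v1 couples the transversion-axis persistence (RY) weighted by the
pyrimidine/purine balance ξ with the transition/transversion axis (KM),
scaled by the sequence's information content H. v2 is the detrended
counterpart built purely from DFA exponents. v3 mixes the strong/weak-bond
axis across the two estimators and tracks GC-content-driven structure.

For exponents in (0, 1) the inner logarithm ln(2 − e) lies in (0, ln 2),
so the outer argument is positive and all three indices are defined (and,
for exponents and ξ in the empirical mtDNA range, negative).
"""

from __future__ import annotations

import dataclasses
import math

from .composition import summarize
from .scaling import dfa_exponent, fractal_dimension, hurst_rs
from .seqio import NucleotideSequence
from .walks import RULES, map_steps


class IndexDomainError(ValueError):
    """Raised when an index's logarithm argument is not strictly positive."""


def _check_exponent(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise IndexDomainError(f"{name} must lie in (0, 1), got {value}")


def v1(H: float, xi: float, alpha_RY: float, alpha_KM: float) -> float:
    """v1 = H · ln(α′_RY · ξ · ln(α′_KM)) with α′ = 2 − α."""
    _check_exponent("alpha_RY", alpha_RY)
    _check_exponent("alpha_KM", alpha_KM)
    if xi is None or xi <= 0.0:
        raise IndexDomainError(f"xi must be positive and defined, got {xi}")
    if H <= 0.0:
        raise IndexDomainError(f"H must be positive, got {H}")
    inner = fractal_dimension(alpha_RY) * xi * math.log(fractal_dimension(alpha_KM))
    if inner <= 0.0:
        raise IndexDomainError(f"v1 inner argument {inner} is not positive")
    return H * math.log(inner)


def v2(beta_RY: float, beta_KM: float) -> float:
    """v2 = ln(β′_RY · ln(β′_KM)) with β′ = 2 − β."""
    _check_exponent("beta_RY", beta_RY)
    _check_exponent("beta_KM", beta_KM)
    inner = fractal_dimension(beta_RY) * math.log(fractal_dimension(beta_KM))
    if inner <= 0.0:
        raise IndexDomainError(f"v2 inner argument {inner} is not positive")
    return math.log(inner)


def v3(beta_SW: float, alpha_SW: float) -> float:
    """v3 = ln(β′_SW · ln(α′_SW)) with α′, β′ = 2 − exponent."""
    _check_exponent("beta_SW", beta_SW)
    _check_exponent("alpha_SW", alpha_SW)
    inner = fractal_dimension(beta_SW) * math.log(fractal_dimension(alpha_SW))
    if inner <= 0.0:
        raise IndexDomainError(f"v3 inner argument {inner} is not positive")
    return math.log(inner)


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Per-sequence features: composition, six exponents and the indices.

    ``D`` and ``C`` are carried for export even though they do not enter
    v1–v3 (they track H almost linearly on real mtDNA compositions); when a
    vector is built from published exponent tables they are NaN.
    """

    id: str
    xi: float
    H: float
    D: float
    C: float
    alpha_RY: float
    alpha_SW: float
    alpha_KM: float
    beta_RY: float
    beta_SW: float
    beta_KM: float
    v1: float
    v2: float
    v3: float

    @classmethod
    def from_measurements(
        cls,
        id: str,
        xi: float,
        H: float,
        alpha_RY: float,
        alpha_SW: float,
        alpha_KM: float,
        beta_RY: float,
        beta_SW: float,
        beta_KM: float,
        D: float = math.nan,
        C: float = math.nan,
    ) -> "FeatureVector":
        """Build a vector from already-measured statistics, recomputing v1–v3.

        This is the route for published exponent tables, where the raw
        sequences are not re-analysed.
        """
        return cls(
            id=id, xi=xi, H=H, D=D, C=C,
            alpha_RY=alpha_RY, alpha_SW=alpha_SW, alpha_KM=alpha_KM,
            beta_RY=beta_RY, beta_SW=beta_SW, beta_KM=beta_KM,
            v1=v1(H, xi, alpha_RY, alpha_KM),
            v2=v2(beta_RY, beta_KM),
            v3=v3(beta_SW, alpha_SW),
        )

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.v1, self.v2, self.v3)


def build_feature_vector(
    seq: NucleotideSequence,
    l_min: int = 4,
    l_max: int | None = None,
    n_windows: int = 40,
) -> FeatureVector:
    """Run the full per-sequence pipeline: walks → exponents → indices.

    Encodes the sequence under all three rules, estimates the Hurst (R/S)
    and DFA exponents for each, summarizes the composition, and combines
    everything into (v1, v2, v3). Degenerate-series and domain errors from
    the sub-steps propagate with the sequence id attached.
    """
    try:
        alphas, betas = {}, {}
        for rule in RULES:
            steps = map_steps(seq, rule)
            alphas[rule] = hurst_rs(steps, l_min=l_min, l_max=l_max, n_windows=n_windows).exponent
            betas[rule] = dfa_exponent(steps, l_min=l_min, l_max=l_max, n_windows=n_windows).exponent
        comp = summarize(seq)
        if not comp.xi_defined:
            raise IndexDomainError("Chargaff ratio undefined (no purines)")
        return FeatureVector(
            id=seq.id,
            xi=comp.xi,
            H=comp.H,
            D=comp.D,
            C=comp.C,
            alpha_RY=alphas["RY"], alpha_SW=alphas["SW"], alpha_KM=alphas["KM"],
            beta_RY=betas["RY"], beta_SW=betas["SW"], beta_KM=betas["KM"],
            v1=v1(comp.H, comp.xi, alphas["RY"], alphas["KM"]),
            v2=v2(betas["RY"], betas["KM"]),
            v3=v3(betas["SW"], alphas["SW"]),
        )
    except ValueError as exc:
        raise type(exc)(f"sequence {seq.id!r}: {exc}") from exc
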