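"""Small-angle X-ray scattering: Debye profiles, Guinier and P(r) analysis.

Theoretical scattering of a coordinate model via the Debye equation
(point scatterers, atomic Gaussian-sum form factors with excluded-solvent
correction, or one-bead-per-residue coarse graining for large models),
Guinier fitting with a self-consistent q*Rg window, pair-distance
distribution both directly from coordinates and by regularized indirect
transform of a measured profile, and the reduced chi-square comparing a
scaled model curve with experiment.

Units: q in 1/A, distances in A, intensities arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .structio import Structure, electron_count

__all__ = [
    "ScatteringProfile",
    "GuinierFit",
    "PofR",
    "ChiSquareFit",
    "debye_profile",
    "radius_of_gyration",
    "guinier_fit",
    "pair_distribution",
    "chi_square",
    "read_dat",
    "write_dat",
]

SOLVENT_DENSITY = 0.334  # e/A^3, bulk water

# Cromer-Mann 4-Gaussian coefficients: f(q) = sum a_i exp(-b_i (q/4pi)^2) + c
CROMER_MANN: dict[str, tuple[list[float], list[float], float]] = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
    "P": ([6.43450, 4.17910, 1.78000, 1.49080],
          [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
    "MG": ([5.42040, 2.17350, 1.22690, 2.30730],
           [2.82750, 79.2611, 0.380800, 7.19370], 0.858400),
    "FE": ([11.7695, 7.35730, 3.52220, 2.30450],
           [4.76110, 0.307200, 15.3535, 76.8805], 1.03690),
    "ZN": ([14.0743, 7.03180, 5.16520, 2.41000],
           [3.26550, 0.233300, 10.3163, 58.7097], 1.30410),
}

# displaced solvent volumes (A^3) per heavy element (Fraser-type dummy atoms)
DISPLACED_VOLUME: dict[str, float] = {
    "H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "S": 19.86, "P": 5.73,
    "MG": 20.0, "FE": 7.99, "ZN": 9.85,
}


@dataclass
class ScatteringProfile:
    """Intensity on a strictly increasing nonnegative q-grid."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be matching 1-D arrays")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be nonnegative and strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class GuinierFit:
    rg: float  # A
    i0: float
    q_range_used: tuple[float, float]
    r_value: float  # correlation of the ln I vs q^2 fit
    n_points: int

    def to_dict(self) -> dict:
        return {
            "rg_A": self.rg,
            "i0": self.i0,
            "qmin": self.q_range_used[0],
            "qmax": self.q_range_used[1],
            "r_value": self.r_value,
            "n_points": self.n_points,
        }


@dataclass
class PofR:
    r: np.ndarray
    p: np.ndarray  # normalized: integral of p dr = 1
    dmax: float

    def rg(self) -> float:
        """Real-space radius of gyration: Rg^2 = integral p r^2 dr / 2."""
        return float(np.sqrt(np.trapezoid(self.p * self.r**2, self.r) / 2.0))


@dataclass
class ChiSquareFit:
    chi2: float
    scale: float
    constant: float
    n_points: int

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "scale": self.scale,
                "constant": self.constant, "n_points": self.n_points}


def atomic_form_factor(element: str, q: np.ndarray) -> np.ndarray:
    """In-vacuo X-ray form factor f(q) for a neutral atom (4-Gaussian fit;
    unknown elements fall back to the flat electron count)."""
    el = element.strip().upper()
    cm = CROMER_MANN.get(el)
    if cm is None:
        return np.full_like(np.asarray(q, dtype=float), float(electron_count(el)))
    a, b, c = cm
    s2 = (np.asarray(q, dtype=float) / (4.0 * np.pi)) ** 2
    f = np.full_like(s2, c)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


def excluded_solvent_factor(element: str, q: np.ndarray,
                            solvent_density: float = SOLVENT_DENSITY) -> np.ndarray:
    """Gaussian dummy-atom scattering of the solvent displaced by an atom."""
    v = DISPLACED_VOLUME.get(element.strip().upper(), 16.44)
    q = np.asarray(q, dtype=float)
    return solvent_density * v * np.exp(-(q**2) * v ** (2.0 / 3.0) / (4.0 * np.pi))


def _gather_scatterers(structure: Structure, mode: str,
                       q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (N,3) and per-scatterer form factors (N, len(q))."""
    if mode == "residue":
        coords, fconst = [], []
        for chain in structure.chains:
            for res in chain.residues:
                if res.is_water:
                    continue
                if not res.atoms:
                    continue
                pos = np.mean([a.position for a in res.atoms], axis=0)
                ne = sum(electron_count(a.element) for a in res.atoms)
                coords.append(pos)
                fconst.append(float(ne))
        coords = np.asarray(coords)
        f = np.repeat(np.asarray(fconst)[:, None], len(q), axis=1)
        return coords, f
    atoms = [a for a in structure.atoms()
             if a.residue_name not in ("HOH", "WAT")]
    coords = np.array([a.position for a in atoms])
    if mode == "point":
        f = np.array([[float(electron_count(a.element))] * len(q) for a in atoms])
    elif mode == "atomic":
        f = np.array([
            atomic_form_factor(a.element, q) - excluded_solvent_factor(a.element, q)
            for a in atoms
        ])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return coords, f


def debye_profile(
    structure: Structure,
    q_grid: np.ndarray,
    mode: str = "auto",
    coarse_grain_threshold: int = 10_000,
) -> ScatteringProfile:
    """Orientationally averaged intensity by the Debye double sum.

    I(q) = sum_ij f_i(q) f_j(q) sinc(q r_ij).  ``mode``:

    * ``point``   — constant f = electron count per atom
    * ``atomic``  — 4-Gaussian form factors minus excluded-solvent term
    * ``residue`` — one bead per residue, f = residue electron count
    * ``auto``    — atomic, switching to residue above
      ``coarse_grain_threshold`` atoms (the sum is O(N^2))
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or len(q) == 0:
        raise ValueError("q_grid must be a non-empty 1-D array")
    n_atoms = sum(1 for a in structure.atoms())
    if n_atoms == 0:
        raise ValueError("structure has no atoms")
    if mode == "auto":
        mode = "residue" if n_atoms > coarse_grain_threshold else "atomic"
    coords, f = _gather_scatterers(structure, mode, q)
    n = len(coords)
    intensity = np.zeros(len(q))
    # pairwise distances in blocks to bound memory at ~block*n floats
    block = max(1, int(5e6 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = np.linalg.norm(coords[start:stop, None, :] - coords[None, :, :], axis=2)
        for k, qk in enumerate(q):
            sinc = np.sinc(qk * d / np.pi)  # np.sinc(x) = sin(pi x)/(pi x)
            intensity[k] += np.einsum("i,ij,j->", f[start:stop, k], sinc, f[:, k])
    return ScatteringProfile(q=q, intensity=intensity)


def radius_of_gyration(structure: Structure,
                       weights: str = "electrons") -> float:
    """Direct-space radius of gyration over all atoms.

    Rg^2 = sum w_i |r_i - rbar|^2 / sum w_i with the weighted centroid
    rbar; weights are electron counts (``"electrons"``) or uniform
    (``"uniform"``).
    """
    atoms = [a for a in structure.atoms()
             if a.residue_name not in ("HOH", "WAT")]
    if not atoms:
        raise ValueError("structure has no atoms")
    coords = np.array([a.position for a in atoms])
    if weights == "electrons":
        w = np.array([float(electron_count(a.element)) for a in atoms])
    elif weights == "uniform":
        w = np.ones(len(atoms))
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    centroid = (w[:, None] * coords).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((coords - centroid) ** 2).sum(axis=1)).sum() / w.sum()))


def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.3,
                qmin: float | None = None) -> GuinierFit:
    """Guinier analysis: ln I = ln I0 - (Rg^2 / 3) q^2 at low q.

    The window is the largest low-q stretch satisfying qmax * Rg <=
    ``qrg_limit``, found self-consistently (fit, shrink, refit).
    """
    q = profile.q
    I = profile.intensity
    mask = (I > 0) & (q > (qmin if qmin is not None else 0.0))
    q, I = q[mask], I[mask]
    if len(q) < 5:
        raise ValueError("fewer than 5 usable points for Guinier analysis")
    n_window = len(q)
    for _ in range(100):
        qw, iw = q[:n_window], I[:n_window]
        if len(qw) < 5:
            raise ValueError("no Guinier region: window shrank below 5 points")
        x, y = qw**2, np.log(iw)
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            raise ValueError("no Guinier region: nonnegative slope in ln I vs q^2")
        rg = float(np.sqrt(-3.0 * slope))
        new_n = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        new_n = max(new_n, 5)
        if new_n >= n_window:
            r = float(np.corrcoef(x, y)[0, 1])
            return GuinierFit(rg=rg, i0=float(np.exp(intercept)),
                              q_range_used=(float(qw[0]), float(qw[-1])),
                              r_value=r, n_points=len(qw))
        n_window = new_n
    raise ValueError("Guinier window failed to converge")


def _pofr_from_structure(structure: Structure, n_bins: int = 200) -> PofR:
    atoms = list(structure.atoms())
    coords = np.array([a.position for a in atoms])
    w = np.array([float(electron_count(a.element)) for a in atoms])
    from scipy.spatial.distance import pdist

    d = pdist(coords)
    wpair = pdist(w[:, None], metric=lambda u, v: u[0] * v[0])
    dmax = float(d.max()) if len(d) else 0.0
    if dmax == 0.0:
        raise ValueError("need at least two distinct atoms for P(r)")
    hist, edges = np.histogram(d, bins=n_bins, range=(0.0, dmax), weights=wpair)
    r = 0.5 * (edges[:-1] + edges[1:])
    p = hist.astype(float)
    area = np.trapezoid(p, r)
    return PofR(r=r, p=p / area, dmax=dmax)


def _pofr_from_profile(profile: ScatteringProfile, dmax: float,
                       n_r: int = 101,
                       alpha: float | None = None) -> tuple[PofR, float]:
    """Regularized indirect transform at fixed dmax; returns (PofR, chi2).

    The second-difference smoothness weight is auto-scaled to the data:
    candidate weights are scanned and the smoothest solution whose chi2
    stays within a factor 2 of the best is kept (pass ``alpha`` for a
    fixed relative weight instead).
    """
    if profile.sigma is None:
        raise ValueError("indirect transform requires experimental sigmas")
    q = profile.q
    I = profile.intensity
    sig = profile.sigma
    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    # I(q) = integral p(r) sinc(q r) dr, trapezoid weights
    wts = np.full(n_r, dr)
    wts[0] = wts[-1] = dr / 2.0
    qr = np.outer(q, r)
    A = np.sinc(qr / np.pi) * wts[None, :]
    Aw = A / sig[:, None]
    yw = I / sig
    # second-difference smoothness penalty; endpoints pinned to zero
    D = np.zeros((n_r - 2, n_r))
    for i in range(n_r - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    pin = np.zeros((2, n_r))
    pin[0, 0] = pin[1, -1] = np.linalg.norm(Aw) * 10.0
    scale0 = np.linalg.norm(Aw) / np.linalg.norm(D)
    rhs = np.concatenate([yw, np.zeros(n_r - 2 + 2)])

    def solve(lam: float) -> tuple[np.ndarray, float]:
        M = np.vstack([Aw, lam * D, pin])
        p, _ = nnls(M, rhs, maxiter=30 * n_r)
        resid = Aw @ p - yw
        return p, float((resid**2).sum() / max(len(q) - 1, 1))

    if alpha is not None:
        p, chi2 = solve(alpha * scale0)
    else:
        trials = [solve(scale0 * 10.0**e) for e in (-5, -4, -3, -2, -1)]
        chi_min = min(c for _, c in trials)
        # smoothest acceptable fit (the classic L-curve compromise)
        p, chi2 = next((pc for pc in reversed(trials)
                        if pc[1] <= 2.0 * chi_min + 1e-12), trials[0])
    area = np.trapezoid(p, r)
    if area <= 0:
        return PofR(r=r, p=p, dmax=dmax), np.inf
    return PofR(r=r, p=p / area, dmax=dmax), chi2


def pair_distribution(
    source: Structure | ScatteringProfile,
    dmax_search: tuple[float, float, int] | None = None,
    alpha: float | None = None,
) -> PofR:
    """Pair-distance distribution P(r).

    From a :class:`Structure`: electron-weighted pair-distance histogram
    with dmax = the maximum pairwise distance.  From a measured profile:
    smoothness-regularized indirect transform; dmax is chosen over
    ``dmax_search = (lo, hi, n)`` by the best compromise of fit quality
    and a vanishing, nonnegative P at the endpoint.
    """
    if isinstance(source, Structure):
        return _pofr_from_structure(source)
    if dmax_search is None:
        raise ValueError("profile input requires a dmax_search range")
    lo, hi, n = dmax_search
    if n < 1 or hi <= lo:
        raise ValueError("empty dmax search range")
    candidates: list[tuple[float, PofR]] = []
    for dmax in np.linspace(lo, hi, n):
        pofr, chi2 = _pofr_from_profile(source, float(dmax), alpha=alpha)
        # penalize mass piled against the dmax endpoint (tail should decay)
        tail = float(pofr.p[-5:].mean() / max(pofr.p.max(), 1e-30))
        candidates.append((chi2 * (1.0 + 5.0 * tail), pofr))
    best_score = min(s for s, _ in candidates)
    # an over-large dmax fits equally well with an empty tail, so prefer
    # the most compact support whose fit is within 10% of the best
    for score, pofr in candidates:
        if score <= 1.10 * best_score + 1e-12:
            return pofr
    return candidates[0][1]


def chi_square(calc: ScatteringProfile, exp: ScatteringProfile) -> ChiSquareFit:
    """Reduced chi-square of a model profile against experiment.

    The model is interpolated onto the experimental q-grid and fitted with
    a free scale c and constant offset b (closed-form weighted least
    squares); chi2 = 1/(N-1) sum ((c I_calc + b - I_exp)/sigma)^2.
    """
    if exp.sigma is None:
        raise ValueError("experimental profile must carry sigmas")
    if np.any(exp.sigma == 0):
        raise ValueError("experimental sigmas contain zeros")
    qmin, qmax = calc.q[0], calc.q[-1]
    mask = (exp.q >= qmin) & (exp.q <= qmax)
    if mask.sum() < 3:
        raise ValueError("model and experimental q-ranges barely overlap")
    qe = exp.q[mask]
    ye = exp.intensity[mask]
    se = exp.sigma[mask]
    a = np.interp(qe, calc.q, calc.intensity)
    w = 1.0 / se**2
    sw, swa, swy = w.sum(), (w * a).sum(), (w * ye).sum()
    swaa, sway = (w * a * a).sum(), (w * a * ye).sum()
    det = sw * swaa - swa**2
    if abs(det) < 1e-300:
        raise ValueError("degenerate model profile (constant intensity)")
    c = (sw * sway - swa * swy) / det
    b = (swaa * swy - swa * sway) / det
    resid = (c * a + b - ye) / se
    chi2 = float((resid**2).sum() / max(len(qe) - 1, 1))
    return ChiSquareFit(chi2=chi2, scale=float(c), constant=float(b),
                        n_points=int(mask.sum()))


def read_dat(path: str | Path) -> ScatteringProfile:
    """Read a 3-column (q, I[, sigma]) whitespace-delimited SAXS profile.

    Comment lines (#) and non-numeric header/footer rows are skipped with
    a warning; fewer than 5 valid rows is an error.
    """
    rows: list[list[float]] = []
    n_skipped = 0
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        try:
            vals = [float(x) for x in parts[:3]]
        except ValueError:
            n_skipped += 1
            continue
        if len(vals) >= 2:
            rows.append(vals)
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-numeric line(s)")
    if len(rows) < 5:
        raise ValueError(f"{path}: fewer than 5 valid data rows")
    has_sigma = all(len(r) >= 3 for r in rows)
    arr = np.array([r[:3] if has_sigma else r[:2] for r in rows])
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    keep = np.concatenate([[True], np.diff(arr[:, 0]) > 0])
    arr = arr[keep]
    return ScatteringProfile(
        q=arr[:, 0], intensity=arr[:, 1],
        sigma=arr[:, 2] if has_sigma else None,
    )


def write_dat(profile: ScatteringProfile, path: str | Path,
              header: str = "q(1/A) I(a.u.) sigma") -> None:
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    data = np.column_stack(cols)
    np.savetxt(path, data, header=header, fmt="%.8e")
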