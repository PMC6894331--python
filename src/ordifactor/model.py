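"""Model specification and implied moments for ordinal CFA under the
theta parameterization.

A :class:`ModelSpec` is a flat parameter system: every cell of every
model matrix (loadings, factor covariances, residual variances,
thresholds, factor means, and the second-order / MIMIC extras) holds
either a fixed value or an index into one shared free-parameter vector.
Equality constraints — within or across groups — are expressed by
assigning the same index to several cells, so multi-group invariance
models need no special bookkeeping in the fitting code.

Implied moments per group: the latent-response covariance
``Sigma* = Lambda Psi Lambda' + Theta`` is rescaled to correlation
metric by its own diagonal, and thresholds are shifted by the implied
means ``Lambda alpha`` and rescaled by the same diagonal factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Slot", "ParamAllocator", "ModelSpec", "implied_stat_vector",
           "implied_jacobian"]

FIXED = -1


@dataclass
class Slot:
    """One model matrix: integer parameter ids (FIXED = -1) plus the
    values used where a cell is fixed."""

    idx: np.ndarray
    fix: np.ndarray

    @classmethod
    def fixed(cls, values) -> "Slot":
        v = np.asarray(values, dtype=float)
        return cls(idx=np.full(v.shape, FIXED, dtype=int), fix=v)

    def fill(self, theta: np.ndarray) -> np.ndarray:
        out = self.fix.copy()
        mask = self.idx >= 0
        out[mask] = theta[self.idx[mask]]
        return out


class ParamAllocator:
    """Allocates free-parameter ids with names, starts and bounds."""

    def __init__(self):
        self.names: list[str] = []
        self.start: list[float] = []
        self.lower: list[float] = []
        self.upper: list[float] = []

    def new(self, name: str, start: float, lower: float = -np.inf,
            upper: float = np.inf) -> int:
        self.names.append(name)
        self.start.append(start)
        self.lower.append(lower)
        self.upper.append(upper)
        return len(self.names) - 1

    @property
    def n(self) -> int:
        return len(self.names)


@dataclass
class ModelSpec:
    kind: str                     # "cfa" | "second_order" | "mimic"
    items: list[str]              # modeled variables (MIMIC: indicators then causes)
    n_categories: list[int]
    factors: list[str]
    groups: list
    slots: dict = field(default_factory=dict)   # (group_index, slot_name) -> Slot
    param_names: list[str] = field(default_factory=list)
    start: np.ndarray = None
    lower: np.ndarray = None
    upper: np.ndarray = None
    n_xvars: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def slot(self, g: int, name: str) -> Slot:
        return self.slots[(g, name)]

    def finish(self, alloc: ParamAllocator) -> "ModelSpec":
        self.param_names = alloc.names
        self.start = np.array(alloc.start, dtype=float)
        self.lower = np.array(alloc.lower, dtype=float)
        self.upper = np.array(alloc.upper, dtype=float)
        return self

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "items": list(self.items),
            "n_categories": [int(k) for k in self.n_categories],
            "factors": list(self.factors),
            "groups": [str(g) for g in self.groups],
            "n_xvars": self.n_xvars,
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (str, int, float, list, dict))},
            "param_names": list(self.param_names),
            "start": self.start.tolist(),
            "lower": [None if not np.isfinite(v) else float(v)
                      for v in self.lower],
            "upper": [None if not np.isfinite(v) else float(v)
                      for v in self.upper],
            "slots": {f"{g}:{name}": {"idx": slot.idx.tolist(),
                                      "fix": slot.fix.tolist()}
                      for (g, name), slot in self.slots.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        spec = cls(kind=data["kind"], items=data["items"],
                   n_categories=data["n_categories"],
                   factors=data["factors"], groups=data["groups"],
                   n_xvars=data.get("n_xvars", 0),
                   meta=data.get("meta", {}))
        spec.param_names = data["param_names"]
        spec.start = np.asarray(data["start"], dtype=float)
        spec.lower = np.array([-np.inf if v is None else v
                               for v in data["lower"]], dtype=float)
        spec.upper = np.array([np.inf if v is None else v
                               for v in data["upper"]], dtype=float)
        for key, s in data["slots"].items():
            g, name = key.split(":", 1)
            spec.slots[(int(g), name)] = Slot(
                idx=np.asarray(s["idx"], dtype=int),
                fix=np.asarray(s["fix"], dtype=float))
        return spec

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml
        return cls.from_dict(yaml.safe_load(open(path)))

    # -- structural matrices per group ---------------------------------
    def group_matrices(self, g: int, theta: np.ndarray) -> dict:
        """All filled model matrices for group g, plus Sigma, tau, mu."""
        kind = self.kind
        if kind == "mimic":
            return self._mimic_matrices(g, theta)
        out = {"L": self.slot(g, "lambda").fill(theta),
               "Th": self.slot(g, "theta").fill(theta),
               "tau": self.slot(g, "tau").fill(theta),
               "alpha": self.slot(g, "alpha").fill(theta)}
        if kind == "second_order":
            out["gamma"] = self.slot(g, "gamma").fill(theta)
            out["phi"] = self.slot(g, "phi").fill(theta)[0]
            out["d"] = self.slot(g, "disturb").fill(theta)
            out["Psi"] = (out["phi"] * np.outer(out["gamma"], out["gamma"])
                          + np.diag(out["d"]))
        else:
            out["Psi"] = self.slot(g, "psi").fill(theta)
        out["mu"] = out["L"] @ out["alpha"]
        out["Sigma"] = out["L"] @ out["Psi"] @ out["L"].T + np.diag(out["Th"])
        return out

    def group_structure(self, g: int, theta: np.ndarray):
        """Return (Sigma, tau_flat, mu) for group g."""
        m = self.group_matrices(g, theta)
        return m["Sigma"], m["tau"], m["mu"]

    def _mimic_matrices(self, g: int, theta: np.ndarray) -> dict:
        L = self.slot(g, "lambda").fill(theta)        # p_ind x (1 + m_sub)
        psi_sub = self.slot(g, "psi_sub").fill(theta)  # m_sub diag
        psi_z = self.slot(g, "psi_zeta").fill(theta)[0]
        beta = self.slot(g, "beta").fill(theta)        # q
        Phix = self.slot(g, "phix").fill(theta)        # q x q
        Th = self.slot(g, "theta").fill(theta)         # p_ind
        tau = self.slot(g, "tau").fill(theta)          # all variables
        lg = L[:, 0]
        Ls = L[:, 1:]
        var_eta = float(beta @ Phix @ beta + psi_z)
        Syy = var_eta * np.outer(lg, lg) + Ls @ np.diag(psi_sub) @ Ls.T + np.diag(Th)
        Syx = np.outer(lg, Phix @ beta)
        Sigma = np.block([[Syy, Syx], [Syx.T, Phix]])
        mu = np.zeros(Sigma.shape[0])
        return {"L": L, "psi_sub": psi_sub, "psi_z": psi_z, "beta": beta,
                "Phix": Phix, "Th": Th, "tau": tau, "lg": lg, "Ls": Ls,
                "var_eta": var_eta, "Sigma": Sigma, "mu": mu}


def implied_jacobian(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d sigma / d theta of the implied stat vector.

    Every free parameter contributes a structured perturbation
    (dSigma, dmu, dtau) per group; the chain rule through the
    correlation-metric rescaling is uniform:

      dP_jk   = dSigma_jk/(s_j s_k)
                - P_jk (dSigma_jj/Sigma_jj + dSigma_kk/Sigma_kk)/2
      dtau*_r = (dtau_r - dmu_j)/s_j - tau*_r dSigma_jj/(2 Sigma_jj)

    Shared (equality-constrained) parameters accumulate over all the
    cells and groups they occupy.
    """
    ncat = np.asarray(spec.n_categories)
    p = len(spec.items)
    n_tau = int(np.sum(ncat - 1))
    iu = np.triu_indices(p, 1)
    q_g = n_tau + len(iu[0])
    item_of_flat = np.repeat(np.arange(p), ncat - 1)
    J = np.zeros((q_g * spec.n_groups, spec.n_free))

    for g in range(spec.n_groups):
        M = spec.group_matrices(g, theta)
        Sigma, tau, mu = M["Sigma"], M["tau"], M["mu"]
        dg = np.diag(Sigma)
        s = np.sqrt(np.maximum(dg, 1e-8))
        P = Sigma / np.outer(s, s)
        tau_std = (tau - mu[item_of_flat]) / s[item_of_flat]
        off = g * q_g

        def emit(pid, D=None, dmu=None, dtau_r=None):
            """Accumulate one parameter's contribution for this group."""
            if D is not None:
                dd = np.diag(D)
                rel = dd / dg
                J[off + n_tau:off + q_g, pid] += (
                    D[iu] / (s[iu[0]] * s[iu[1]])
                    - 0.5 * P[iu] * (rel[iu[0]] + rel[iu[1]]))
                J[off:off + n_tau, pid] += (-0.5 * tau_std
                                            * rel[item_of_flat])
            if dmu is not None:
                J[off:off + n_tau, pid] += -dmu[item_of_flat] / s[item_of_flat]
            if dtau_r is not None:
                r, val = dtau_r
                J[off + r, pid] += val / s[item_of_flat[r]]

        # thresholds: direct
        tau_slot = spec.slot(g, "tau")
        for r, pid in enumerate(tau_slot.idx):
            if pid >= 0:
                emit(pid, dtau_r=(r, 1.0))

        if spec.kind == "mimic":
            _mimic_jac(spec, g, M, emit, p)
            continue

        L, Psi, alpha = M["L"], M["Psi"], M["alpha"]
        LP = L @ Psi
        lam_slot = spec.slot(g, "lambda")
        for a in range(p):
            for b in range(L.shape[1]):
                pid = lam_slot.idx[a, b]
                if pid < 0:
                    continue
                D = np.zeros((p, p))
                D[a, :] += LP[:, b]
                D[:, a] += LP[:, b]
                dmu = np.zeros(p)
                dmu[a] = alpha[b]
                emit(pid, D=D, dmu=dmu if alpha[b] != 0 else None)

        th_slot = spec.slot(g, "theta")
        for a, pid in enumerate(th_slot.idx):
            if pid >= 0:
                D = np.zeros((p, p))
                D[a, a] = 1.0
                emit(pid, D=D)

        al_slot = spec.slot(g, "alpha")
        for b, pid in enumerate(al_slot.idx):
            if pid >= 0:
                emit(pid, dmu=L[:, b])

        if spec.kind == "second_order":
            gam, phi = M["gamma"], M["phi"]
            Lg = L @ gam
            gam_slot = spec.slot(g, "gamma")
            for f, pid in enumerate(gam_slot.idx):
                if pid >= 0:
                    emit(pid, D=phi * (np.outer(L[:, f], Lg)
                                       + np.outer(Lg, L[:, f])))
            pid = spec.slot(g, "phi").idx[0]
            if pid >= 0:
                emit(pid, D=np.outer(Lg, Lg))
            dis_slot = spec.slot(g, "disturb")
            for f, pid in enumerate(dis_slot.idx):
                if pid >= 0:
                    emit(pid, D=np.outer(L[:, f], L[:, f]))
        else:
            psi_slot = spec.slot(g, "psi")
            m = Psi.shape[0]
            for b in range(m):
                for c in range(b, m):
                    pid = psi_slot.idx[b, c]
                    if pid < 0:
                        continue
                    if b == c:
                        D = np.outer(L[:, b], L[:, b])
                    else:
                        D = np.outer(L[:, b], L[:, c]) + np.outer(L[:, c],
                                                                  L[:, b])
                    emit(pid, D=D)
    return J


def _mimic_jac(spec, g, M, emit, p):
    """Parameter contributions for the MIMIC structure."""
    lg, Ls, beta, Phix = M["lg"], M["Ls"], M["beta"], M["Phix"]
    var_eta = M["var_eta"]
    pi = lg.shape[0]          # indicators
    q = Phix.shape[0]
    xb = Phix @ beta
    lam_slot = spec.slot(g, "lambda")
    for j in range(pi):
        pid = lam_slot.idx[j, 0]
        if pid >= 0:
            D = np.zeros((p, p))
            D[j, :pi] += var_eta * lg
            D[:pi, j] += var_eta * lg
            D[j, pi:] += xb
            D[pi:, j] += xb
            emit(pid, D=D)
        for f in range(Ls.shape[1]):
            pid = lam_slot.idx[j, f + 1]
            if pid >= 0:
                D = np.zeros((p, p))
                D[j, :pi] += Ls[:, f]
                D[:pi, j] += Ls[:, f]
                emit(pid, D=D)
    pid = spec.slot(g, "psi_zeta").idx[0]
    if pid >= 0:
        D = np.zeros((p, p))
        D[:pi, :pi] = np.outer(lg, lg)
        emit(pid, D=D)
    beta_slot = spec.slot(g, "beta")
    for r, pid in enumerate(beta_slot.idx):
        if pid >= 0:
            D = np.zeros((p, p))
            D[:pi, :pi] = 2.0 * xb[r] * np.outer(lg, lg)
            D[:pi, pi:] += np.outer(lg, Phix[:, r])
            D[pi:, :pi] += np.outer(Phix[:, r], lg)
            emit(pid, D=D)
    phix_slot = spec.slot(g, "phix")
    for a in range(q):
        for b in range(a + 1, q):
            pid = phix_slot.idx[a, b]
            if pid < 0:
                continue
            D = np.zeros((p, p))
            D[:pi, :pi] = 2.0 * beta[a] * beta[b] * np.outer(lg, lg)
            dxb = np.zeros(q)
            dxb[a] = beta[b]
            dxb[b] = beta[a]
            D[:pi, pi:] += np.outer(lg, dxb)
            D[pi:, :pi] += np.outer(dxb, lg)
            D[pi + a, pi + b] += 1.0
            D[pi + b, pi + a] += 1.0
            emit(pid, D=D)


def implied_stat_vector(spec: ModelSpec, theta: np.ndarray,
                        sd_floor: float = 1e-8) -> np.ndarray:
    """Implied [standardized thresholds; correlations] stacked over groups,
    ordered exactly like ``PolychoricSummary.stat_vector``."""
    ncat = np.asarray(spec.n_categories)
    out = []
    for g in range(spec.n_groups):
        Sigma, tau, mu = spec.group_structure(g, theta)
        d = np.diag(Sigma)
        sd = np.sqrt(np.maximum(d, sd_floor))
        P = Sigma / np.outer(sd, sd)
        # thresholds item-major
        pos = 0
        taus = np.empty(tau.shape)
        for j, k in enumerate(ncat):
            nt = k - 1
            taus[pos:pos + nt] = (tau[pos:pos + nt] - mu[j]) / sd[j]
            pos += nt
        iu = np.triu_indices(P.shape[0], 1)
        # row-major (j, k) j < k order matches triu_indices
        out.append(np.concatenate([taus, P[iu]]))
    return np.concatenate(out)
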