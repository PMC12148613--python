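"""Compile a :class:`NetworkModel` into a fast ODE right-hand side.

The compiler flattens rules into index arrays (reaction type, reactant /
modifier / gate indices, parameter slots, sparse stoichiometry) and
evaluates rates in a single kernel, JIT-compiled with numba when available
and falling back to the identical pure-Python loop otherwise.  An analytic
Jacobian is assembled from the closed-form derivatives of the three rate
laws, which is what keeps the stiff integrator fast enough for the
global-sensitivity sweeps.

State ordering is the species order of the model definition
(``model.species_names``); reversible rules occupy two adjacent reaction
columns (forward, reverse).  Concentrations are clamped at zero inside the
rate evaluation so the derivative stays finite for (slightly) negative
states produced by the integrator; :func:`validate_state` flags genuinely
negative inputs.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .network import INHIBITOR_TARGETS, ModelError, NetworkModel, ParameterSet

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


# reaction type codes
_MA, _MM, _SH, _MMP = 0, 1, 2, 3


@njit(cache=True)
def _rates_kernel(y, p, scale, rtype, r1, r2, mod, kidx, Kidx,
                  gptr, gsp, gK, gsg, rates):
    n = rtype.shape[0]
    for j in range(n):
        k = p[kidx[j]] * scale[j]
        t = rtype[j]
        if t == _MA:
            v = k
            if r1[j] >= 0:
                c = y[r1[j]]
                v *= c if c > 0.0 else 0.0
            if r2[j] >= 0:
                c = y[r2[j]]
                v *= c if c > 0.0 else 0.0
        elif t == _MM:
            S = y[r1[j]]
            S = S if S > 0.0 else 0.0
            E = y[mod[j]]
            E = E if E > 0.0 else 0.0
            v = k * E * S / (p[Kidx[j]] + S)
        elif t == _MMP:
            S = y[r1[j]]
            S = S if S > 0.0 else 0.0
            v = k * S / (p[Kidx[j]] + S)
        else:  # _SH
            M = y[mod[j]]
            M = M if M > 0.0 else 0.0
            v = k * M / (p[Kidx[j]] + M)
            if r1[j] >= 0:
                c = y[r1[j]]
                v *= c if c > 0.0 else 0.0
        for g in range(gptr[j], gptr[j + 1]):
            G = y[gsp[g]]
            G = G if G > 0.0 else 0.0
            Kg = p[gK[g]]
            if gsg[g] > 0:
                v *= G / (Kg + G)
            else:
                v *= Kg / (Kg + G)
        rates[j] = v


@njit(cache=True)
def _rhs_kernel(y, p, scale, rtype, r1, r2, mod, kidx, Kidx,
                gptr, gsp, gK, gsg, sptr, ssp, sco, rates, dy):
    _rates_kernel(y, p, scale, rtype, r1, r2, mod, kidx, Kidx,
                  gptr, gsp, gK, gsg, rates)
    for i in range(dy.shape[0]):
        dy[i] = 0.0
    for j in range(rtype.shape[0]):
        v = rates[j]
        for s in range(sptr[j], sptr[j + 1]):
            dy[ssp[s]] += sco[s] * v


@njit(cache=True)
def _jac_kernel(y, p, scale, rtype, r1, r2, mod, kidx, Kidx,
                gptr, gsp, gK, gsg, sptr, ssp, sco, J):
    n = rtype.shape[0]
    ns = y.shape[0]
    for i in range(ns):
        for jj in range(ns):
            J[i, jj] = 0.0
    # scratch for up to 2 base dependencies + gates
    for j in range(n):
        k = p[kidx[j]] * scale[j]
        t = rtype[j]
        # base value and derivatives w.r.t. dependencies
        d1 = -1
        d2 = -1
        dv1 = 0.0
        dv2 = 0.0
        if t == _MA:
            a = 1.0
            b = 1.0
            if r1[j] >= 0:
                a = y[r1[j]]
                a = a if a > 0.0 else 0.0
            if r2[j] >= 0:
                b = y[r2[j]]
                b = b if b > 0.0 else 0.0
            base = k * a * b
            if r1[j] >= 0:
                d1 = r1[j]
                dv1 = k * b if (y[r1[j]] > 0.0) else 0.0
            if r2[j] >= 0:
                d2 = r2[j]
                dv2 = k * a if (y[r2[j]] > 0.0) else 0.0
            if r1[j] >= 0 and r1[j] == r2[j]:
                # same species twice: v = k*c^2, dv/dc = 2*k*c
                d2 = -1
                dv1 = 2.0 * k * a if (y[r1[j]] > 0.0) else 0.0
        elif t == _MM:
            S = y[r1[j]]
            S = S if S > 0.0 else 0.0
            E = y[mod[j]]
            E = E if E > 0.0 else 0.0
            Km = p[Kidx[j]]
            base = k * E * S / (Km + S)
            d1 = r1[j]
            dv1 = (k * E * Km / ((Km + S) * (Km + S))) if y[r1[j]] > 0.0 else 0.0
            d2 = mod[j]
            dv2 = (k * S / (Km + S)) if y[mod[j]] > 0.0 else 0.0
        elif t == _MMP:
            S = y[r1[j]]
            S = S if S > 0.0 else 0.0
            Km = p[Kidx[j]]
            base = k * S / (Km + S)
            d1 = r1[j]
            dv1 = (k * Km / ((Km + S) * (Km + S))) if y[r1[j]] > 0.0 else 0.0
        else:  # _SH
            M = y[mod[j]]
            M = M if M > 0.0 else 0.0
            K = p[Kidx[j]]
            sat = M / (K + M)
            if r1[j] >= 0:
                S = y[r1[j]]
                S = S if S > 0.0 else 0.0
                base = k * S * sat
                d1 = r1[j]
                dv1 = k * sat if y[r1[j]] > 0.0 else 0.0
                d2 = mod[j]
                dv2 = (k * S * K / ((K + M) * (K + M))) if y[mod[j]] > 0.0 else 0.0
            else:
                base = k * sat
                d1 = mod[j]
                dv1 = (k * K / ((K + M) * (K + M))) if y[mod[j]] > 0.0 else 0.0
        # gate product
        gprod = 1.0
        for g in range(gptr[j], gptr[j + 1]):
            G = y[gsp[g]]
            G = G if G > 0.0 else 0.0
            Kg = p[gK[g]]
            gprod *= (G / (Kg + G)) if gsg[g] > 0 else (Kg / (Kg + G))
        # contributions from base dependencies
        for s in range(sptr[j], sptr[j + 1]):
            c = sco[s]
            row = ssp[s]
            if d1 >= 0 and dv1 != 0.0:
                J[row, d1] += c * dv1 * gprod
            if d2 >= 0 and dv2 != 0.0:
                J[row, d2] += c * dv2 * gprod
        # contributions from gate species
        for g in range(gptr[j], gptr[j + 1]):
            if y[gsp[g]] <= 0.0:
                # gate derivative still nonzero at G=0+ for activating gates,
                # but the clamp makes dG/dy zero for y<0; use y>=0 -> deriv
                if y[gsp[g]] < 0.0:
                    continue
            G = y[gsp[g]]
            G = G if G > 0.0 else 0.0
            Kg = p[gK[g]]
            gother = 1.0
            for h in range(gptr[j], gptr[j + 1]):
                if h == g:
                    continue
                Gh = y[gsp[h]]
                Gh = Gh if Gh > 0.0 else 0.0
                Kh = p[gK[h]]
                gother *= (Gh / (Kh + Gh)) if gsg[h] > 0 else (Kh / (Kh + Gh))
            dg = Kg / ((Kg + G) * (Kg + G))
            if gsg[g] < 0:
                dg = -dg
            contrib = base * gother * dg
            for s in range(sptr[j], sptr[j + 1]):
                J[ssp[s], gsp[g]] += sco[s] * contrib


def validate_state(y, species_names, tol=0.0) -> list:
    """Names of species whose state is below ``-tol`` (negative input flag)."""
    y = np.asarray(y)
    return [species_names[i] for i in np.nonzero(y < -tol)[0]]


class CompiledModel:
    """A NetworkModel flattened to arrays, with rate/RHS/Jacobian evaluators.

    The object is also directly callable as ``f(state, time)`` using the
    parameters it was compiled with (inhibitors attached to the model are
    honoured through their ``apply_time``).
    """

    def __init__(self, model: NetworkModel, params: ParameterSet):
        model.validate_parameters(params)
        self.model = model
        self.params = params
        self.species_names = model.species_names
        self.n_species = len(self.species_names)
        self._sindex = {n: i for i, n in enumerate(self.species_names)}

        cols = model.expanded_reactions()
        self.reactions = cols
        n_rx = len(cols)
        rtype = np.zeros(n_rx, np.int32)
        r1 = np.full(n_rx, -1, np.int32)
        r2 = np.full(n_rx, -1, np.int32)
        mod = np.full(n_rx, -1, np.int32)
        kidx = np.zeros(n_rx, np.int32)
        Kidx = np.full(n_rx, -1, np.int32)
        inh = np.zeros((len(INHIBITOR_TARGETS), n_rx), bool)
        nc = np.zeros(n_rx, bool)
        gptr = [0]
        gsp, gK, gsg = [], [], []
        sptr = [0]
        ssp, sco = [], []

        law_code = {"mass_action": _MA, "michaelis_menten": _MM,
                    "saturating_hill": _SH}
        for j, (r, direction) in enumerate(cols):
            nc[j] = r.non_conserving
            if direction > 0:
                code = law_code[r.rate_law]
                if code == _MM and r.modifier is None:
                    code = _MMP
                rtype[j] = code
                rs = list(r.reactants)
                if rs:
                    r1[j] = self._sindex[rs[0]]
                if len(rs) > 1:
                    r2[j] = self._sindex[rs[1]]
                if r.modifier is not None:
                    mod[j] = self._sindex[r.modifier]
                kidx[j] = params.index(r.rate_constant_key)
                if r.km_key:
                    Kidx[j] = params.index(r.km_key)
                for tgt in r.inhibitor_target:
                    inh[INHIBITOR_TARGETS.index(tgt), j] = True
                for g in r.gates:
                    gsp.append(self._sindex[g.species])
                    gK.append(params.index(g.k_key))
                    gsg.append(g.sign)
                st = r.stoichiometry()
            else:
                # reverse of a reversible rule: mass action on the products
                rtype[j] = _MA
                ps = list(r.products)
                if len(ps) > 2:
                    raise ModelError(
                        f"rule {r.name}: reversible rules need <=2 products")
                if ps:
                    r1[j] = self._sindex[ps[0]]
                if len(ps) > 1:
                    r2[j] = self._sindex[ps[1]]
                kidx[j] = params.index(r.reverse_key)
                st = {s: -c for s, c in r.stoichiometry().items()}
            gptr.append(len(gsp))
            for s, c in st.items():
                ssp.append(self._sindex[s])
                sco.append(float(c))
            sptr.append(len(ssp))

        self._arr = (
            rtype, r1, r2, mod, kidx, Kidx,
            np.array(gptr, np.int32), np.array(gsp, np.int32),
            np.array(gK, np.int32), np.array(gsg, np.int32),
            np.array(sptr, np.int32), np.array(ssp, np.int32),
            np.array(sco, np.float64),
        )
        self.n_reactions = n_rx
        self.nc_mask = nc
        self.inh_mask = inh
        self._pvec = params.vector()
        self._rates_buf = np.zeros(n_rx)

        # observable weight matrix
        self.obs_names = list(model.observables)
        W = np.zeros((len(self.obs_names), self.n_species))
        for i, name in enumerate(self.obs_names):
            for s, w in model.observables[name].items():
                W[i, self._sindex[s]] = w
        self.obs_matrix = W

        # monomer bookkeeping for conservation reports
        self.monomers = model.monomers()
        self.monomer_matrix = model.monomer_matrix()

    # -- construction helpers ---------------------------------------------
    def species_index(self, name) -> int:
        return self._sindex[name]

    def initial_state(self, pvec=None) -> np.ndarray:
        p = self._pvec if pvec is None else np.asarray(pvec)
        y0 = np.zeros(self.n_species)
        for i, s in enumerate(self.model.species):
            if s.initial_value_key:
                y0[i] = p[self.params.index(s.initial_value_key)]
        return y0

    def inhibitor_scale(self, t, inhibitors=None) -> np.ndarray:
        """Per-reaction multiplier at time ``t`` given active inhibitors."""
        scale = np.ones(self.n_reactions)
        specs = list(self.model.inhibitors) + list(inhibitors or [])
        for spec in specs:
            if t >= spec.apply_time:
                mask = self.inh_mask[INHIBITOR_TARGETS.index(spec.target)]
                scale[mask] *= (1.0 - spec.fraction)
        return scale

    # -- evaluators --------------------------------------------------------
    def rates(self, y, pvec=None, scale=None) -> np.ndarray:
        p = self._pvec if pvec is None else np.asarray(pvec, float)
        s = np.ones(self.n_reactions) if scale is None else scale
        out = np.zeros(self.n_reactions)
        _rates_kernel(np.asarray(y, float), p, s, *self._arr[:10], out)
        return out

    def rhs(self, pvec=None, scale=None):
        """Return f(t, y) -> dy/dt for fixed parameters and inhibitor scale."""
        p = self._pvec if pvec is None else np.ascontiguousarray(pvec, float)
        s = np.ones(self.n_reactions) if scale is None else \
            np.ascontiguousarray(scale, float)
        arr = self._arr
        nrx = self.n_reactions

        def f(t, y, _p=p, _s=s):
            dy = np.zeros(y.shape[0])
            _rhs_kernel(y, _p, _s, *arr, np.zeros(nrx), dy)
            return dy

        return f

    def jac(self, pvec=None, scale=None):
        p = self._pvec if pvec is None else np.ascontiguousarray(pvec, float)
        s = np.ones(self.n_reactions) if scale is None else \
            np.ascontiguousarray(scale, float)
        arr = self._arr
        ns = self.n_species

        def J(t, y, _p=p, _s=s):
            out = np.zeros((ns, ns))
            _jac_kernel(y, _p, _s, *arr, out)
            return out

        return J

    def __call__(self, state, time=0.0):
        scale = self.inhibitor_scale(time)
        return self.rhs(scale=scale)(time, np.asarray(state, float))

    def observe(self, states) -> np.ndarray:
        """Map a (t x species) state matrix to (t x observable)."""
        return np.asarray(states) @ self.obs_matrix.T

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for r, d in self.reactions:
            h.update(f"{r.name}:{d}".encode())
        h.update(self.params.fingerprint().encode())
        return h.hexdigest()[:16]


def compile_rhs(model: NetworkModel, params: ParameterSet) -> CompiledModel:
    """Flatten ``model`` against ``params``; raises ModelError naming any
    unresolvable parameter key."""
    return CompiledModel(model, params)
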