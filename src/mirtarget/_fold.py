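"""Secondary-structure folding engine (reduced nearest-neighbour model).

The model scores a non-crossing secondary structure by loop
decomposition:

* stacked pair regions contribute tabulated stacking free energies
  (Watson-Crick and G:U pairs),
* hairpin and internal/bulge loops contribute affine costs
  ``init + slope * n_unpaired``,
* multiloops contribute ``a + b * (branches + 1) + c * n_unpaired``,
* the exterior loop is free,
* for two-molecule folds, any structure with at least one
  intermolecular pair pays a single duplex initiation cost, and every
  loop containing the cut point between the molecules is scored like
  an exterior loop (no cost, no minimum hairpin size).

There are no dangling ends and no coaxial stacking.  Internal loops
are capped at ``max_interior`` unpaired bases (never reached by the
short sequences the enumeration oracle handles).

Two independent routes are provided: dynamic programming (minimum
free energy with traceback, and McCaskill-style partition function)
and exhaustive enumeration with :func:`structure_energy`, used as a
brute-force oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

GAS_CONSTANT = 0.0019872041  # kcal/(mol*K)
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: canonical pairs, including the G:U wobble
_PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}

MIN_HAIRPIN = 3


def encode(seq: str) -> np.ndarray:
    """Integer codes for an RNA string; N (unpairable) maps to 4."""
    return np.array([BASE_INDEX.get(ch, 4) for ch in seq], dtype=np.int8)


@dataclass
class EnergyModel:
    """Parameter set of the reduced nearest-neighbour model.

    Energies are free energies in kcal/mol at ``temperature`` degrees
    Celsius.  ``stack[a, b, c, d]`` is the stacking energy of outer
    pair a-b on inner pair c-d, i.e. the motif 5'-a c-3' / 3'-b d-5';
    +inf marks non-pairing combinations.
    """

    temperature: float = 37.0
    stack: np.ndarray | None = None
    hairpin_init: float = 5.6
    hairpin_per_nt: float = 0.3
    internal_init: float = 4.0
    internal_per_nt: float = 0.5
    ml_init: float = 4.6
    ml_branch: float = 0.4
    ml_unpaired: float = 0.1
    duplex_init: float = 4.09
    max_interior: int = 30

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * (self.temperature + 273.15)

    @classmethod
    def default(cls) -> "EnergyModel":
        """Model with the stacking table shipped in ``data/``."""
        path = resources.files("mirtarget").joinpath("data/stack_energies.tsv")
        return cls(stack=load_stack_table(path.read_text()))

    def validate(self) -> None:
        if self.stack is None:
            raise ValueError("stack table missing")
        for (x, w), (y, z) in (
            ((a, b), (c, d))
            for a, b in _WC
            for c, d in _WC
        ):
            e = self.stack[BASE_INDEX[x], BASE_INDEX[w], BASE_INDEX[y], BASE_INDEX[z]]
            if not e <= 0:
                raise ValueError(f"WC/WC stack {x}{y}/{w}{z} must be <= 0, got {e}")

    def stack_energy(self, a: int, b: int, c: int, d: int) -> float:
        if max(a, b, c, d) > 3:
            return math.inf
        return float(self.stack[a, b, c, d])


def load_stack_table(text: str) -> np.ndarray:
    """Parse the tab-separated stacking table (kcal/mol).

    Columns: outer pair (two bases), inner pair (two bases), energy.
    The thermodynamic symmetry stack(XY/WZ) == stack(ZW/YX) is
    enforced on load.
    """
    table = np.full((4, 4, 4, 4), np.inf)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        outer, inner, value = line.split("\t")
        x, w = (BASE_INDEX[ch] for ch in outer)
        y, z = (BASE_INDEX[ch] for ch in inner)
        table[x, w, y, z] = float(value)
    for x in range(4):
        for w in range(4):
            for y in range(4):
                for z in range(4):
                    a, b = table[x, w, y, z], table[z, y, w, x]
                    if np.isfinite(a) != np.isfinite(b) or (
                        np.isfinite(a) and abs(a - b) > 1e-9
                    ):
                        raise ValueError(
                            "stack table violates rotational symmetry at "
                            f"{BASES[x]}{BASES[y]}/{BASES[w]}{BASES[z]}"
                        )
    return table


def can_pair(a: int, b: int) -> bool:
    if a > 3 or b > 3:
        return False
    return (BASES[a], BASES[b]) in _PAIRABLE


def _pair_ok_matrix(
    codes: np.ndarray,
    cut: int | None,
    constraint: np.ndarray | None,
) -> np.ndarray:
    """Boolean matrix of admissible pairs (i, j), i < j.

    A pair needs at least ``MIN_HAIRPIN`` enclosed positions unless it
    spans the cut; constrained (forced single-stranded) positions never
    pair.
    """
    n = len(codes)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if not can_pair(int(codes[i]), int(codes[j])):
                continue
            spans = cut is not None and i < cut <= j
            if not spans and j - i - 1 < MIN_HAIRPIN:
                continue
            if constraint is not None and (constraint[i] or constraint[j]):
                continue
            ok[i, j] = True
    return ok


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle


def enumerate_pairings(
    codes: np.ndarray,
    cut: int | None = None,
    constraint: np.ndarray | None = None,
    max_len: int = 14,
):
    """Yield every admissible non-crossing pair set exactly once."""
    n = len(codes)
    if n > max_len:
        raise ValueError(f"sequence of length {n} exceeds enumeration cap {max_len}")
    ok = _pair_ok_matrix(codes, cut, constraint)

    def gen(i: int, j: int):
        if i > j:
            yield ()
            return
        # position i unpaired
        yield from gen(i + 1, j)
        for k in range(i + 1, j + 1):
            if ok[i, k]:
                for left in gen(i + 1, k - 1):
                    for right in gen(k + 1, j):
                        yield ((i, k),) + left + right

    yield from gen(0, n - 1)


def structure_energy(
    codes: np.ndarray,
    pairs,
    model: EnergyModel,
    cut: int | None = None,
) -> float:
    """Loop-decomposition energy of one structure (kcal/mol).

    Independent of the dynamic programming recursions; used to score
    enumerated structures.
    """
    pairs = sorted(pairs)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    energy = 0.0
    has_cross = cut is not None and any(i < cut <= j for i, j in pairs)
    for i, j in pairs:
        # walk the loop closed by (i, j)
        branches = []
        unpaired = 0
        p = i + 1
        while p < j:
            if p in partner and partner[p] > p:
                branches.append((p, partner[p]))
                p = partner[p] + 1
            else:
                unpaired += 1
                p += 1
        loop_has_cut = (
            cut is not None
            and i < cut <= j
            and not any(k < cut <= l for k, l in branches)
        )
        if loop_has_cut:
            continue  # exterior-like loop, no cost
        if not branches:
            energy += model.hairpin_init + model.hairpin_per_nt * unpaired
        elif len(branches) == 1:
            k, l = branches[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                energy += model.stack_energy(
                    int(codes[i]), int(codes[j]), int(codes[k]), int(codes[l])
                )
            elif s1 + s2 > model.max_interior:
                return math.inf
            else:
                energy += model.internal_init + model.internal_per_nt * (s1 + s2)
        else:
            energy += (
                model.ml_init
                + model.ml_branch * (len(branches) + 1)
                + model.ml_unpaired * unpaired
            )
    if has_cross:
        energy += model.duplex_init
    return energy


# ---------------------------------------------------------------------------
# Dynamic programming


class FoldEngine:
    """MFE and partition-function folding under an :class:`EnergyModel`."""

    def __init__(self, model: EnergyModel | None = None):
        self.model = model if model is not None else EnergyModel.default()
        self.model.validate()

    # -- public API --------------------------------------------------------

    def mfe(
        self,
        codes: np.ndarray,
        cut: int | None = None,
        constraint: np.ndarray | None = None,
        allow_cross: bool = True,
    ) -> tuple[float, list[tuple[int, int]]]:
        """Minimum free energy and one optimal structure.

        The returned energy excludes the duplex initiation term (added
        by the caller for two-molecule folds).
        """
        if cut is not None and not allow_cross:
            e_a, p_a = self.mfe(codes[:cut])
            e_b, p_b = self.mfe(codes[cut:])
            return e_a + e_b, p_a + [(i + cut, j + cut) for i, j in p_b]
        state = self._dp(codes, cut, constraint, mode="mfe")
        energy = state["F"][len(codes) - 1] if len(codes) else 0.0
        pairs = self._traceback(state)
        return float(energy), pairs

    def partition(
        self,
        codes: np.ndarray,
        cut: int | None = None,
        constraint: np.ndarray | None = None,
    ) -> float:
        """Partition function (duplex initiation excluded)."""
        if len(codes) == 0:
            return 1.0
        state = self._dp(codes, cut, constraint, mode="pf")
        return float(state["F"][len(codes) - 1])

    def ensemble_free_energy(
        self,
        codes: np.ndarray,
        constraint: np.ndarray | None = None,
    ) -> float:
        """-RT ln Z of a single molecule."""
        return -self.model.rt * math.log(self.partition(codes, None, constraint))

    def duplex_mfe(self, codes_a: np.ndarray, codes_b: np.ndarray):
        """MFE of the two-molecule system, duplex initiation included.

        Returns ``(energy, pairs, n)`` with pair indices on the
        concatenation of the two molecules.
        """
        codes = np.concatenate([codes_a, codes_b])
        cut = len(codes_a)
        e_intra, p_intra = self.mfe(codes, cut, allow_cross=False)
        e_all, p_all = self.mfe(codes, cut, allow_cross=True)
        e_cross = e_all + self.model.duplex_init
        if e_cross < e_intra:
            return e_cross, p_all, len(codes)
        return e_intra, p_intra, len(codes)

    def duplex_partition(self, codes_a: np.ndarray, codes_b: np.ndarray) -> float:
        """Partition function of the pair, duplex initiation included."""
        codes = np.concatenate([codes_a, codes_b])
        cut = len(codes_a)
        z_all = self.partition(codes, cut)
        z_intra = self.partition(codes_a) * self.partition(codes_b)
        z_cross = max(z_all - z_intra, 0.0)
        return z_cross * math.exp(-self.model.duplex_init / self.model.rt) + z_intra

    # -- recursions --------------------------------------------------------

    def _dp(self, codes, cut, constraint, mode):
        m = self.model
        rt = m.rt
        n = len(codes)
        ok = _pair_ok_matrix(codes, cut, constraint)
        mfe = mode == "mfe"
        BAD = math.inf if mfe else 0.0
        V = np.full((n, n), BAD)
        M = np.full((n, n), BAD)   # multiloop region, >= 1 branch
        M1 = np.full((n, n), BAD)  # multiloop region, branch starts at i

        sizes = np.arange(n + 2, dtype=float)
        if mfe:
            hp = m.hairpin_init + m.hairpin_per_nt * sizes
            interior_w = m.internal_init + m.internal_per_nt * sizes
            wu = m.ml_unpaired * sizes
            wb = m.ml_branch
            wml_close = m.ml_init + m.ml_branch
        else:
            hp = np.exp(-(m.hairpin_init + m.hairpin_per_nt * sizes) / rt)
            interior_w = np.exp(-(m.internal_init + m.internal_per_nt * sizes) / rt)
            wu = np.exp(-m.ml_unpaired * sizes / rt)
            wb = math.exp(-m.ml_branch / rt)
            wml_close = math.exp(-(m.ml_init + m.ml_branch) / rt)
        mi = m.max_interior
        kern = np.add.outer(sizes[: mi + 1], sizes[: mi + 1])
        kernel = (
            m.internal_init + m.internal_per_nt * kern
            if mfe
            else np.exp(-(m.internal_init + m.internal_per_nt * kern) / rt)
        )

        def is_intra(i, j):
            return cut is None or j < cut or i >= cut

        def stack_w(i, j):
            e = m.stack_energy(
                int(codes[i]), int(codes[j]), int(codes[i + 1]), int(codes[j - 1])
            )
            if mfe:
                return e
            return 0.0 if math.isinf(e) else math.exp(-e / rt)

        def interior_term(i, j, s1_hi, s2_hi):
            """Stack + internal-loop contributions for pair (i, j)."""
            if s1_hi < 0 or s2_hi < 0:
                return BAD
            sub = V[i + 1 : i + 2 + s1_hi, j - 1 - s2_hi : j][:, ::-1]
            kk = kernel[: s1_hi + 1, : s2_hi + 1].copy()
            # cap total size
            tot = kern[: s1_hi + 1, : s2_hi + 1]
            if mfe:
                kk[tot > mi] = math.inf
                vals = sub + kk
                vals[0, 0] = sub[0, 0] + stack_w(i, j)
                return float(vals.min(initial=math.inf))
            kk[tot > mi] = 0.0
            vals = sub * kk
            vals[0, 0] = sub[0, 0] * stack_w(i, j)
            return float(vals.sum())

        def combine(*vals):
            return min(vals) if mfe else sum(vals)

        # --- phase 1: all cells in increasing span; cross cells deferred
        cross_cells = []
        for d in range(1, n):
            for i in range(0, n - d):
                j = i + d
                if ok[i, j]:
                    if is_intra(i, j):
                        V[i, j] = self._cell_intra(
                            i, j, V, M, M1, hp, interior_term, wml_close, mfe
                        )
                    else:
                        cross_cells.append((i, j))
                if is_intra(i, j):
                    # M1: branch starting at i, trailing unpaired
                    ls = np.arange(i + 1, j + 1)
                    vrow = V[i, i + 1 : j + 1]
                    if mfe:
                        M1[i, j] = float(
                            np.min(vrow + wb + wu[j - ls], initial=math.inf)
                        )
                    else:
                        M1[i, j] = float(np.dot(vrow, wu[j - ls]) * wb)
                    # M: split at the start k of the last branch; the
                    # leading region i..k-1 is all-unpaired or contains
                    # earlier branches (M[i, k-1])
                    ks = np.arange(i, j + 1)
                    m1col = M1[i : j + 1, j]
                    if mfe:
                        lead_branch = np.concatenate(([math.inf], M[i, i:j]))
                        lead = np.minimum(wu[ks - i], lead_branch)
                        M[i, j] = float(np.min(lead + m1col, initial=math.inf))
                    else:
                        lead = wu[ks - i] + np.concatenate(([0.0], M[i, i:j]))
                        M[i, j] = float(np.dot(lead, m1col))

        # --- phase 2/3: cofold-specific arrays and cross cells
        Fl = Fr = None
        if cut is not None:
            Fl, Fr = self._edge_arrays(codes, cut, V, ok, mfe)
            u0 = wu  # cost of an all-unpaired multiloop stretch
            for i, j in sorted(cross_cells, key=lambda c: c[1] - c[0]):
                V[i, j] = self._cell_cross(
                    i, j, cut, V, M, Fl, Fr, interior_term, u0, wb, wml_close, mfe
                )

        # --- phase 4: exterior
        F = np.zeros(n) if mfe else np.ones(n)
        Fext = np.concatenate(([0.0 if mfe else 1.0], F))  # offset by 1
        for j in range(n):
            col = V[: j + 1, j]
            if mfe:
                Fext[j + 1] = min(
                    Fext[j], float(np.min(Fext[: j + 1] + col, initial=math.inf))
                )
            else:
                Fext[j + 1] = Fext[j] + float(np.dot(Fext[: j + 1], col))
        return {
            "codes": codes,
            "cut": cut,
            "ok": ok,
            "V": V,
            "M": M,
            "M1": M1,
            "F": Fext[1:],
            "Fl": Fl,
            "Fr": Fr,
            "hp": hp,
            "interior_term": interior_term,
            "wu": wu,
            "wb": wb,
            "wml_close": wml_close,
            "mfe": mfe,
        }

    def _cell_intra(self, i, j, V, M, M1, hp, interior_term, wml_close, mfe):
        m = self.model
        size = j - i - 1
        vals = [hp[size]]
        s_hi = min(m.max_interior, j - i - 2)
        if j - i >= 2:
            vals.append(interior_term(i, j, min(s_hi, j - i - 2), min(s_hi, j - i - 2)))
        if j - i >= 3:
            # multiloop: M[i+1, k-1] + M1[k, j-1], k in [i+2, j-2]
            ks = np.arange(i + 2, j - 1)
            if len(ks):
                lead = M[i + 1, ks - 1]
                tail = M1[ks, j - 1]
                if mfe:
                    vals.append(float(np.min(lead + tail, initial=math.inf)) + wml_close)
                else:
                    vals.append(float(np.dot(lead, tail)) * wml_close)
        return min(vals) if mfe else sum(vals)

    def _edge_arrays(self, codes, cut, V, ok, mfe):
        """Exterior-like arrays abutting the cut.

        ``Fl[a]`` covers region a..cut-1 (indices 0..cut, Fl[cut] empty);
        ``Fr[b]`` covers region cut..b (index cut-1 means empty).
        """
        n = len(codes)
        if mfe:
            Fl = np.zeros(cut + 1)
            for a in range(cut - 1, -1, -1):
                best = Fl[a + 1]
                for k in range(a + 1, cut):
                    if ok[a, k]:
                        best = min(best, V[a, k] + Fl[k + 1])
                Fl[a] = best
            fr = {cut - 1: 0.0}
            for b in range(cut, n):
                best = fr[b - 1]
                for k in range(cut, b):
                    if ok[k, b]:
                        best = min(best, fr[k - 1] + V[k, b])
                fr[b] = best
            return Fl, fr
        Fl = np.ones(cut + 1)
        for a in range(cut - 1, -1, -1):
            tot = Fl[a + 1]
            for k in range(a + 1, cut):
                tot += V[a, k] * Fl[k + 1]
            Fl[a] = tot
        fr = {cut - 1: 1.0}
        for b in range(cut, n):
            tot = fr[b - 1]
            for k in range(cut, b):
                tot += fr[k - 1] * V[k, b]
            fr[b] = tot
        return Fl, fr

    def _mlfree(self, a, b, M, wu, mfe):
        """Multiloop-context region a..b with >= 0 branches (intra)."""
        if a > b:
            return 0.0 if mfe else 1.0
        empty = wu[b - a + 1]
        if mfe:
            return min(empty, M[a, b])
        return empty + M[a, b]

    def _cell_cross(self, i, j, cut, V, M, Fl, Fr, interior_term, wu, wb, wml_close, mfe):
        m = self.model
        # (a) loop containing the cut: two free regions
        vals = [Fl[i + 1] + Fr[j - 1] if mfe else Fl[i + 1] * Fr[j - 1]]
        # (b) interior loop whose single branch spans the cut
        s1_hi = min(m.max_interior, cut - 1 - (i + 1))
        s2_hi = min(m.max_interior, j - 1 - cut)
        if s1_hi >= 0 and s2_hi >= 0:
            vals.append(interior_term(i, j, s1_hi, s2_hi))
        # (c) multiloop with the cut-spanning branch plus >= 1 intra branch
        acc = math.inf if mfe else 0.0
        for k in range(i + 1, cut):
            for l in range(cut, j):
                if not np.isfinite(V[k, l]) if mfe else V[k, l] == 0.0:
                    continue
                left_e = wu[k - 1 - i] if k - 1 >= i + 1 else (0.0 if mfe else 1.0)
                right_e = wu[j - 1 - l] if l + 1 <= j - 1 else (0.0 if mfe else 1.0)
                if mfe:
                    lm = M[i + 1, k - 1] if k - 1 >= i + 1 else math.inf
                    rm = M[l + 1, j - 1] if l + 1 <= j - 1 else math.inf
                    side = min(lm + min(rm, right_e), left_e + rm)
                    acc = min(acc, V[k, l] + wb + side)
                else:
                    lf = self._mlfree(i + 1, k - 1, M, wu, mfe)
                    rf = self._mlfree(l + 1, j - 1, M, wu, mfe)
                    both = lf * rf - left_e * right_e
                    acc += V[k, l] * wb * both
        if mfe:
            if math.isfinite(acc):
                vals.append(acc + wml_close)
        else:
            vals.append(acc * wml_close)
        return min(vals) if mfe else sum(vals)

    # -- traceback ---------------------------------------------------------

    def _traceback(self, state) -> list[tuple[int, int]]:
        if not state["mfe"]:
            raise ValueError("traceback requires an MFE fold")
        codes = state["codes"]
        cut = state["cut"]
        V, M, M1, F = state["V"], state["M"], state["M1"], state["F"]
        Fl, Fr = state["Fl"], state["Fr"]
        hp, wu, wb, wml_close = state["hp"], state["wu"], state["wb"], state["wml_close"]
        n = len(codes)
        pairs: list[tuple[int, int]] = []
        close = lambda a, b: abs(a - b) <= 1e-7

        def fval(j):
            return F[j] if j >= 0 else 0.0

        tasks: list[tuple] = [("EXT", n - 1)] if n else []
        while tasks:
            task = tasks.pop()
            kind = task[0]
            if kind == "EXT":
                j = task[1]
                if j < 0:
                    continue
                if close(fval(j), fval(j - 1)):
                    tasks.append(("EXT", j - 1))
                    continue
                for k in range(j + 1):
                    if np.isfinite(V[k, j]) and close(fval(j), fval(k - 1) + V[k, j]):
                        pairs.append((k, j))
                        tasks.append(("V", k, j))
                        tasks.append(("EXT", k - 1))
                        break
            elif kind == "V":
                i, j = task[1], task[2]
                target = V[i, j]
                if self._trace_v(
                    i, j, target, codes, cut, V, M, M1, Fl, Fr,
                    hp, wu, wb, wml_close, pairs, tasks, close,
                ):
                    continue
            elif kind == "M":
                i, j = task[1], task[2]
                target = M[i, j]
                done = False
                for k in range(i, j + 1):
                    lead = wu[k - i]
                    if np.isfinite(M1[k, j]) and close(target, lead + M1[k, j]):
                        tasks.append(("M1", k, j))
                        done = True
                        break
                    if k - 1 >= i and np.isfinite(M[i, k - 1]) and np.isfinite(
                        M1[k, j]
                    ) and close(target, M[i, k - 1] + M1[k, j]):
                        tasks.append(("M", i, k - 1))
                        tasks.append(("M1", k, j))
                        done = True
                        break
                if not done:  # pragma: no cover
                    raise AssertionError("M traceback failed")
            elif kind == "M1":
                i, j = task[1], task[2]
                target = M1[i, j]
                for l in range(i + 1, j + 1):
                    if np.isfinite(V[i, l]) and close(target, V[i, l] + wb + wu[j - l]):
                        pairs.append((i, l))
                        tasks.append(("V", i, l))
                        break
                else:  # pragma: no cover
                    raise AssertionError("M1 traceback failed")
            elif kind == "FL":
                a = task[1]
                if a >= cut:
                    continue
                if close(Fl[a], Fl[a + 1]):
                    tasks.append(("FL", a + 1))
                    continue
                for k in range(a + 1, cut):
                    if np.isfinite(V[a, k]) and close(Fl[a], V[a, k] + Fl[k + 1]):
                        pairs.append((a, k))
                        tasks.append(("V", a, k))
                        tasks.append(("FL", k + 1))
                        break
            elif kind == "FR":
                b = task[1]
                if b <= cut - 1:
                    continue
                if close(Fr[b], Fr[b - 1]):
                    tasks.append(("FR", b - 1))
                    continue
                for k in range(cut, b):
                    if np.isfinite(V[k, b]) and close(Fr[b], Fr[k - 1] + V[k, b]):
                        pairs.append((k, b))
                        tasks.append(("V", k, b))
                        tasks.append(("FR", k - 1))
                        break
        return sorted(pairs)

    def _trace_v(
        self, i, j, target, codes, cut, V, M, M1, Fl, Fr,
        hp, wu, wb, wml_close, pairs, tasks, close,
    ) -> bool:
        m = self.model
        spans = cut is not None and i < cut <= j
        if spans:
            # (a) cut loop
            if close(target, Fl[i + 1] + Fr[j - 1]):
                tasks.append(("FL", i + 1))
                tasks.append(("FR", j - 1))
                return True
            # (b) interior with cut-spanning branch
            for k in range(i + 1, cut):
                for l in range(cut, j):
                    if not np.isfinite(V[k, l]):
                        continue
                    s1, s2 = k - i - 1, j - l - 1
                    if s1 + s2 > m.max_interior:
                        continue
                    e = (
                        m.stack_energy(
                            int(codes[i]), int(codes[j]), int(codes[k]), int(codes[l])
                        )
                        if s1 == 0 and s2 == 0
                        else m.internal_init + m.internal_per_nt * (s1 + s2)
                    )
                    if np.isfinite(e) and close(target, V[k, l] + e):
                        pairs.append((k, l))
                        tasks.append(("V", k, l))
                        return True
            # (c) multiloop with cut-spanning branch
            for k in range(i + 1, cut):
                for l in range(cut, j):
                    if not np.isfinite(V[k, l]):
                        continue
                    for left_m in (False, True):
                        for right_m in (False, True):
                            if not left_m and not right_m:
                                continue
                            le = (
                                M[i + 1, k - 1]
                                if left_m
                                else (wu[k - 1 - i] if k - 1 >= i + 1 else 0.0)
                            )
                            re = (
                                M[l + 1, j - 1]
                                if right_m
                                else (wu[j - 1 - l] if l + 1 <= j - 1 else 0.0)
                            )
                            if left_m and (k - 1 < i + 1 or not np.isfinite(le)):
                                continue
                            if right_m and (l + 1 > j - 1 or not np.isfinite(re)):
                                continue
                            if close(target, V[k, l] + wb + wml_close + le + re):
                                pairs.append((k, l))
                                tasks.append(("V", k, l))
                                if left_m:
                                    tasks.append(("M", i + 1, k - 1))
                                if right_m:
                                    tasks.append(("M", l + 1, j - 1))
                                return True
            raise AssertionError(f"V traceback failed at cross cell ({i}, {j})")
        # hairpin
        if close(target, hp[j - i - 1]):
            return True
        # stack / interior
        for k in range(i + 1, j):
            for l in range(j - 1, k, -1):
                if not np.isfinite(V[k, l]):
                    continue
                s1, s2 = k - i - 1, j - l - 1
                if s1 + s2 > m.max_interior:
                    continue
                e = (
                    m.stack_energy(
                        int(codes[i]), int(codes[j]), int(codes[k]), int(codes[l])
                    )
                    if s1 == 0 and s2 == 0
                    else m.internal_init + m.internal_per_nt * (s1 + s2)
                )
                if np.isfinite(e) and close(target, V[k, l] + e):
                    pairs.append((k, l))
                    tasks.append(("V", k, l))
                    return True
        # multiloop
        for k in range(i + 2, j - 1):
            if (
                np.isfinite(M[i + 1, k - 1])
                and np.isfinite(M1[k, j - 1])
                and close(target, M[i + 1, k - 1] + M1[k, j - 1] + wml_close)
            ):
                tasks.append(("M", i + 1, k - 1))
                tasks.append(("M1", k, j - 1))
                return True
        raise AssertionError(f"V traceback failed at cell ({i}, {j})")
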