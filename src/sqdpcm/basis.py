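"""Gaussian basis sets and shell construction.

Contracted Gaussian basis data are embedded as plain text in the format
``exponent  coeff [coeff ...]`` per primitive, one block per shell.  Two sets
are shipped: cc-pVDZ (the production basis used throughout) and STO-3G (used
as the minimal reference basis for atomic-valence active-space selection).

All basis functions are *pure* (real solid-harmonic) Gaussians; Cartesian
integrals are transformed to the spherical basis after evaluation.  Within a
shell of angular momentum l the m-components are ordered m = -l ... +l
(p shells: y, z, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ANG2BOHR = 1.0 / 0.52917721092  # CODATA 2010, Angstrom -> bohr

# --------------------------------------------------------------------------
# Embedded basis data (public-domain parameters: Dunning 1989; STO-3G,
# Hehre/Stewart/Pople 1969).  Shell letters S/P/D; multiple coefficient
# columns denote general contractions sharing the exponent set.
# --------------------------------------------------------------------------

_CC_PVDZ = {
    "H": """
S
   13.0100      0.0196850
    1.9620      0.1379770
    0.4446      0.4781480
    0.1220      0.5012400
S
    0.1220      1.0000000
P
    0.7270      1.0000000
""",
    "C": """
S
 6665.0000000  0.0006920  -0.0001460
 1000.0000000  0.0053290  -0.0011540
  228.0000000  0.0270770  -0.0057250
   64.7100000  0.1017180  -0.0233120
   21.0600000  0.2747400  -0.0639550
    7.4950000  0.4485640  -0.1499810
    2.7970000  0.2850740  -0.1272620
    0.5215000  0.0152040   0.5445290
    0.1596000 -0.0031910   0.5804960
S
    0.1596000   1.0000000
P
    9.4390000   0.0381090
    2.0020000   0.2094800
    0.5456000   0.5085570
    0.1517000   0.4688420
P
    0.1517000   1.0000000
D
    0.5500000   1.0000000
""",
    "N": """
S
 9046.0000000  0.0007000  -0.0001530
 1357.0000000  0.0053890  -0.0012080
  309.3000000  0.0274060  -0.0059920
   87.7300000  0.1032070  -0.0245440
   28.5600000  0.2787230  -0.0674590
   10.2100000  0.4485400  -0.1580780
    3.8380000  0.2782380  -0.1218310
    0.7466000  0.0154400   0.5490030
    0.2248000  -0.0028640  0.5788150
S
    0.2248000   1.0000000
P
   13.5500000   0.0399190
    2.9170000   0.2171690
    0.7973000   0.5103190
    0.2185000   0.4622060
P
    0.2185000   1.0000000
D
    0.8170000   1.0000000
""",
    "O": """
S
11720.0000000  0.0007100  -0.0001600
 1759.0000000  0.0054700  -0.0012630
  400.8000000  0.0278370  -0.0062670
  113.7000000  0.1048000  -0.0257160
   37.0300000  0.2830620  -0.0709240
   13.2700000  0.4487190  -0.1654110
    5.0250000  0.2709520  -0.1169550
    1.0130000  0.0154580   0.5573680
    0.3023000  -0.0025850  0.5727590
S
    0.3023000   1.0000000
P
   17.7000000   0.0430180
    3.8540000   0.2289130
    1.0460000   0.5087280
    0.2753000   0.4605310
P
    0.2753000   1.0000000
D
    1.1850000   1.0000000
""",
}

_STO_3G = {
    "H": """
S
    3.42525091  0.15432897
    0.62391373  0.53532814
    0.16885540  0.44463454
""",
    "C": """
S
   71.6168370   0.15432897
   13.0450960   0.53532814
    3.5305122   0.44463454
SP
    2.9412494  -0.09996723   0.15591627
    0.6834831   0.39951283   0.60768372
    0.2222899   0.70011547   0.39195739
""",
    "N": """
S
   99.1061690   0.15432897
   18.0523120   0.53532814
    4.8856602   0.44463454
SP
    3.7804559  -0.09996723   0.15591627
    0.8784966   0.39951283   0.60768372
    0.2857144   0.70011547   0.39195739
""",
    "O": """
S
  130.7093200   0.15432897
   23.8088610   0.53532814
    6.4436083   0.44463454
SP
    5.0331513  -0.09996723   0.15591627
    1.1695961   0.39951283   0.60768372
    0.3803890   0.70011547   0.39195739
""",
}

BASIS_LIBRARY = {"cc-pvdz": _CC_PVDZ, "sto-3g": _STO_3G}

_L_OF = {"S": 0, "P": 1, "D": 2, "F": 3}

ELEMENT_Z = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7,
             "O": 8, "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16,
             "Cl": 17}


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Norm of x^l exp(-alpha r^2) (the (l,0,0) Cartesian component)."""
    return (
        (2.0 * alpha / np.pi) ** 0.75
        * (4.0 * alpha) ** (l / 2.0)
        / np.sqrt(_double_factorial(2 * l - 1))
    )


@dataclass
class Shell:
    """One contracted shell on one atom (single contraction column)."""

    l: int
    exps: np.ndarray
    coefs: np.ndarray          # normalized contraction coefficients
    center: np.ndarray         # bohr
    atom_index: int
    ao_offset: int = 0         # spherical AO offset
    cart_offset: int = 0

    @property
    def n_sph(self) -> int:
        return 2 * self.l + 1

    @property
    def n_cart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def _parse_blocks(text: str):
    blocks = []
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        tag = lines[i].strip().upper()
        i += 1
        rows = []
        while i < len(lines) and lines[i].strip().upper() not in _L_OF and \
                lines[i].strip().upper() != "SP":
            rows.append([float(x) for x in lines[i].split()])
            i += 1
        blocks.append((tag, np.array(rows)))
    return blocks


def _normalize_contraction(l: int, exps: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Scale primitive coefficients so the contracted function is unit-norm."""
    c = coefs * np.array([primitive_norm(a, l) for a in exps])
    # overlap of two primitives with the (l,0,0) convention
    s = 0.0
    for i, ai in enumerate(exps):
        for j, aj in enumerate(exps):
            p = ai + aj
            sij = (
                _double_factorial(2 * l - 1)
                * (np.pi / p) ** 1.5
                / (2.0 * p) ** l
            )
            s += c[i] * c[j] * sij
    return c / np.sqrt(s)


def build_shells(elements, coords_bohr, basis_name: str) -> list[Shell]:
    """Expand a molecule into a list of contracted shells.

    General contractions (multiple coefficient columns) become separate
    segmented shells sharing the exponent set.  SP blocks (STO-3G) split
    into an S and a P shell.
    """
    try:
        table = BASIS_LIBRARY[basis_name.lower()]
    except KeyError as exc:
        raise ValueError(f"unknown basis '{basis_name}'") from exc
    shells: list[Shell] = []
    for iat, (el, xyz) in enumerate(zip(elements, coords_bohr)):
        if el not in table:
            raise ValueError(f"no {basis_name} data for element {el}")
        for tag, rows in _parse_blocks(table[el]):
            exps = rows[:, 0]
            if tag == "SP":
                cols = [(0, rows[:, 1]), (1, rows[:, 2])]
            else:
                l = _L_OF[tag]
                cols = [(l, rows[:, 1 + k]) for k in range(rows.shape[1] - 1)]
            for l, raw in cols:
                mask = raw != 0.0
                coefs = _normalize_contraction(l, exps[mask], raw[mask])
                shells.append(Shell(l, exps[mask].copy(), coefs,
                                    np.asarray(xyz, float), iat))
    off = 0
    coff = 0
    for sh in shells:
        sh.ao_offset = off
        sh.cart_offset = coff
        off += sh.n_sph
        coff += sh.n_cart
    return shells


def n_basis(shells) -> int:
    return sum(sh.n_sph for sh in shells)


def ao_labels(shells, elements) -> list[str]:
    """Per-AO labels like '0 C 2s', '1 O 2py' (principal qn by shell count)."""
    labels = []
    # count shells of each l per atom to assign principal quantum numbers
    counts: dict[tuple[int, int], int] = {}
    mnames = {0: [""], 1: ["y", "z", "x"],
              2: ["xy", "yz", "z2", "xz", "x2-y2"],
              3: [f"m{m}" for m in range(-3, 4)]}
    lname = "spdf"
    for sh in shells:
        key = (sh.atom_index, sh.l)
        counts[key] = counts.get(key, 0) + 1
        n = counts[key] + sh.l  # 1s,2s,... / 2p,3p,... / 3d,...
        for m in range(sh.n_sph):
            labels.append(
                f"{sh.atom_index} {elements[sh.atom_index]} "
                f"{n}{lname[sh.l]}{mnames[sh.l][m]}"
            )
    return labels


# --------------------------------------------------------------------------
# Cartesian -> real solid harmonic transforms (common (l,0,0) primitive norm)
# --------------------------------------------------------------------------

_SQRT3 = np.sqrt(3.0)

_C2S = {
    0: np.array([[1.0]]),
    # cart order x,y,z ; sph order m=-1(y), 0(z), +1(x)
    1: np.array([[0.0, 1.0, 0.0],
                 [0.0, 0.0, 1.0],
                 [1.0, 0.0, 0.0]]),
    # cart order xx,xy,xz,yy,yz,zz ; sph order m=-2..+2
    2: np.array([
        [0.0, _SQRT3, 0.0, 0.0, 0.0, 0.0],        # xy
        [0.0, 0.0, 0.0, 0.0, _SQRT3, 0.0],        # yz
        [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],         # (2zz-xx-yy)/2
        [0.0, 0.0, _SQRT3, 0.0, 0.0, 0.0],        # xz
        [_SQRT3 / 2, 0.0, 0.0, -_SQRT3 / 2, 0.0, 0.0],  # (xx-yy)*sqrt3/2
    ]),
}


def c2s_matrix(l: int) -> np.ndarray:
    return _C2S[l]


def cart_components(l: int) -> np.ndarray:
    """(ncart, 3) integer exponents in canonical order (x first)."""
    comps = []
    for i in range(l, -1, -1):
        for j in range(l - i, -1, -1):
            comps.append((i, j, l - i - j))
    return np.array(comps, dtype=np.int64)
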