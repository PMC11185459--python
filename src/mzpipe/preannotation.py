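"""Pre-annotation: group degenerate MS1 features into empirical compounds.

Isotopologues and adducts of one compound appear as separate, co-eluting
features whose m/z values differ by fixed offsets (e.g. +1.003355 Da per
13C, +21.981942 Da between M+H and M+Na). Linking such feature pairs and
laying the connected components onto an isotope x adduct grid yields one
empirical compound per tentative metabolite, so that downstream database
searches query compounds rather than many degenerate features, and a
neutral monoisotopic mass can be inferred by back-calculating ion offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import EmpiricalCompound, FeatureTable, IonRelation

PROTON_MASS = 1.007276
C13_OFFSET = 1.003355

DEFAULT_ISOTOPE_STEPS: list[tuple[str, float]] = [
    ("M0", 0.0),
    ("13C/3C1", C13_OFFSET),
    ("13C/3C2", 2 * C13_OFFSET),
]

DEFAULT_ADDUCTS_POS: list[tuple[str, float]] = [
    ("M+H+", 1.007276),
    ("M+NH4+", 18.033823),
    ("M+Na+", 22.989218),
]

DEFAULT_ADDUCTS_NEG: list[tuple[str, float]] = [
    ("M-H-", -1.007276),
    ("M+Cl-", 34.969402),
    ("M+formate-", 44.998201),
]


def ppm_error(mz_obs: float, mz_ref: float) -> float:
    """Signed mass error of ``mz_obs`` against ``mz_ref`` in parts per million."""
    if mz_ref <= 0:
        raise ValueError("reference m/z must be positive")
    return (mz_obs - mz_ref) / mz_ref * 1e6


@dataclass
class IonTable:
    """The isotope steps and adducts considered during grouping."""

    mode: str = "pos"
    isotope_steps: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_ISOTOPE_STEPS)
    )
    adducts: list[tuple[str, float]] = field(default_factory=lambda: list(DEFAULT_ADDUCTS_POS))

    def __post_init__(self) -> None:
        if self.mode not in ("pos", "neg"):
            raise ValueError("mode must be 'pos' or 'neg'")
        labels = [l for l, _ in self.isotope_steps] + [l for l, _ in self.adducts]
        if len(set(labels)) != len(labels):
            raise ValueError("isotope/adduct labels must be unique")
        if not all(np.isfinite(o) for _, o in self.isotope_steps + self.adducts):
            raise ValueError("mass offsets must be finite")

    @classmethod
    def positive(cls) -> "IonTable":
        return cls(mode="pos")

    @classmethod
    def negative(cls) -> "IonTable":
        return cls(mode="neg", adducts=list(DEFAULT_ADDUCTS_NEG))

    @classmethod
    def from_json(cls, path: str) -> "IonTable":
        import json

        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            mode=doc.get("mode", "pos"),
            isotope_steps=[(str(l), float(o)) for l, o in doc["isotope_steps"]],
            adducts=[(str(l), float(o)) for l, o in doc["adducts"]],
        )

    @property
    def anchor_adduct(self) -> tuple[str, float]:
        """Lowest-offset adduct: the canonical anchor cell at M0."""
        return min(self.adducts, key=lambda la: la[1])


@dataclass
class KhipuGrid:
    """Isotope (rows) x adduct (columns) layout of one feature group."""

    neutral_mass: float
    charge: int
    cells: dict[tuple[str, str], str]  # (isotope_label, adduct_label) -> feature_id

    @property
    def anchor(self) -> tuple[str, str] | None:
        m0_cells = [(iso, add) for (iso, add) in self.cells if iso == "M0"]
        return min(m0_cells, key=lambda c: c[1]) if m0_cells else None


# ---------------------------------------------------------------------------
# pair linking
# ---------------------------------------------------------------------------

def _link_deltas(ion_table: IonTable, charge_states: tuple[int, ...]) -> tuple[
    list[tuple[float, int]], list[tuple[float, int]]
]:
    """(isotope deltas, adduct-pair deltas) in m/z units, with their charge."""
    iso_deltas = []
    for z in charge_states:
        for _, off in ion_table.isotope_steps:
            if off > 0:
                iso_deltas.append((off / z, z))
        # successive isotope gaps (e.g. M+2 vs M+1) reduce to the base step set
    add_deltas = []
    offs = sorted(off for _, off in ion_table.adducts)
    for i in range(len(offs)):
        for j in range(i + 1, len(offs)):
            d = offs[j] - offs[i]
            if d > 0:
                add_deltas.append((d, 1))
    return iso_deltas, add_deltas


def _isotope_ratio_ok(
    intens: np.ndarray, light: int, heavy: int, cap: float
) -> bool:
    """Abundance plausibility gate: heavy/light sample-wise median ratio <= cap."""
    li, hi = intens[light], intens[heavy]
    both = (li > 0) & (hi > 0)
    if not both.any():
        return True  # no shared observations: cannot reject
    return float(np.median(hi[both] / li[both])) <= cap


def candidate_links(
    table: FeatureTable,
    ion_table: IonTable,
    mz_tol_ppm: float = 5.0,
    rt_tol_s: float = 2.0,
    charge_states: tuple[int, ...] = (1,),
    isotope_ratio_cap: float = 1.5,
) -> list[tuple[int, int]]:
    """All feature index pairs linked by an isotope step or adduct-pair delta.

    A pair links when the features co-elute (|delta RT| <= rt_tol_s) and their
    m/z difference matches a known delta within mz_tol_ppm evaluated on the
    heavier member's m/z. Isotope links must additionally pass the abundance
    gate (M+1 cannot exceed ``isotope_ratio_cap`` times M0 in the sample-wise
    median).
    """
    if mz_tol_ppm <= 0 or rt_tol_s <= 0:
        raise ValueError("tolerances must be positive")
    mz = table.mz.to_numpy(dtype=float)
    rt = table.rtime.to_numpy(dtype=float)
    intens = table.intensities.to_numpy(dtype=float)
    iso_deltas, add_deltas = _link_deltas(ion_table, charge_states)
    order = np.argsort(mz)
    max_delta = max([d for d, _ in iso_deltas + add_deltas], default=0.0)
    links: list[tuple[int, int]] = []
    n = len(mz)
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            dmz = mz[j] - mz[i]
            if dmz > max_delta + 0.01:
                break
            if abs(rt[i] - rt[j]) > rt_tol_s:
                continue
            tol_da = mz[j] * mz_tol_ppm * 1e-6
            adduct_hit = any(abs(dmz - d) <= tol_da for d, _ in add_deltas)
            iso_hit = any(abs(dmz - d) <= tol_da for d, _ in iso_deltas) and _isotope_ratio_ok(
                intens, i, j, isotope_ratio_cap
            )
            if adduct_hit or iso_hit:
                links.append((min(i, j), max(i, j)))
    return links


def _connected_components(n: int, links: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in links:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: min(g))


# ---------------------------------------------------------------------------
# grid layout
# ---------------------------------------------------------------------------

def _grid_cells(ion_table: IonTable, charge: int) -> list[tuple[str, str, float]]:
    """(isotope label, adduct label, total mass offset) per grid cell.

    For a cell the observed m/z is (neutral_mass + total offset) / |charge|.
    Multiply-charged grids assume proton adducts (M+zH for positive mode),
    the small-molecule default; only the isotope axis is searched there.
    """
    if charge == 1:
        return [
            (iso_l, add_l, iso_o + add_o)
            for iso_l, iso_o in ion_table.isotope_steps
            for add_l, add_o in ion_table.adducts
        ]
    sign = 1 if ion_table.mode == "pos" else -1
    label = f"M{'+' if sign > 0 else '-'}{charge}H{'+' if sign > 0 else '-'}"
    return [
        (iso_l, label, iso_o + sign * charge * PROTON_MASS)
        for iso_l, iso_o in ion_table.isotope_steps
    ]


def _layout_component(
    comp: list[int],
    mz: np.ndarray,
    ion_table: IonTable,
    mz_tol_ppm: float,
    charge: int = 1,
) -> tuple[float, dict[int, tuple[str, str, float]], list[int]]:
    """Assign component members to isotope x adduct cells.

    Hypotheses: each member could be the M0 ion of each cell's adduct; the
    neutral mass it implies fixes the expected m/z of every other cell. The
    hypothesis assigning the most members wins (ties: smallest total |ppm
    error|, then lowest mass). Cell conflicts keep the feature with smaller
    |ppm error|; evicted features are returned as leftovers.
    Returns (neutral mass, member -> (isotope, adduct, total offset), leftovers).
    """
    cells = _grid_cells(ion_table, charge)
    m0_cells = [c for c in cells if c[0] == "M0"]
    best: tuple[int, float, float, dict[int, tuple[str, str, float]]] | None = None
    for m in comp:
        for _, _, anchor_off in m0_cells:
            neutral = mz[m] * charge - anchor_off
            if neutral <= 0:
                continue
            claims: dict[tuple[str, str], tuple[int, float]] = {}
            assigned: dict[int, tuple[str, str, float]] = {}
            for f in comp:
                best_cell = None
                best_ppm = None
                for iso_l, add_l, total in cells:
                    implied = (neutral + total) / charge
                    err = abs(ppm_error(mz[f], implied))
                    if err <= mz_tol_ppm and (best_ppm is None or err < best_ppm):
                        best_ppm = err
                        best_cell = (iso_l, add_l, total)
                if best_cell is None:
                    continue
                key = (best_cell[0], best_cell[1])
                if key in claims and claims[key][1] <= best_ppm:
                    continue  # existing claimant fits better; f stays unassigned
                if key in claims:
                    assigned.pop(claims[key][0], None)
                claims[key] = (f, best_ppm)
                assigned[f] = best_cell
            total_ppm = sum(err for _, err in claims.values())
            cand = (len(assigned), total_ppm, neutral, assigned)
            if (
                best is None
                or cand[0] > best[0]
                or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
            ):
                best = cand
    if best is None or best[0] < 2:
        return 0.0, {}, list(comp)
    _, _, neutral, assigned = best
    leftovers = [f for f in comp if f not in assigned]
    return neutral, assigned, leftovers


def build_empirical_compounds(
    table: FeatureTable,
    ion_table: IonTable | None = None,
    mz_tol_ppm: float = 5.0,
    rt_tol_s: float = 2.0,
    charge_states: tuple[int, ...] = (1,),
    isotope_ratio_cap: float = 1.5,
) -> list[EmpiricalCompound]:
    """Group a feature table into empirical compounds.

    Every feature ends up in exactly one empirical compound: grouped features
    carry ion relations and an inferred neutral mass; features in no group
    (or evicted in grid-conflict resolution) become singletons with unknown
    ion species and absent neutral mass.
    """
    if ion_table is None:
        ion_table = IonTable.positive()
    if table.n_features == 0:
        return []
    mz = table.mz.to_numpy(dtype=float)
    fids = table.feature_ids
    links = candidate_links(
        table, ion_table, mz_tol_ppm, rt_tol_s, charge_states, isotope_ratio_cap
    )
    components = _connected_components(table.n_features, links)

    raw: list[tuple[float, int, list[tuple[int, tuple[str, str, float] | None]]]] = []
    for comp in components:
        if len(comp) == 1:
            raw.append((mz[comp[0]], 1, [(comp[0], None)]))
            continue
        # try each allowed charge state; keep the layout explaining most members
        neutral, assigned, leftovers, charge = 0.0, {}, list(comp), 1
        for z in charge_states:
            n_z, a_z, l_z = _layout_component(comp, mz, ion_table, mz_tol_ppm, charge=z)
            if len(a_z) > len(assigned):
                neutral, assigned, leftovers, charge = n_z, a_z, l_z, z
        if assigned:
            raw.append(
                (
                    min(mz[f] for f in assigned),
                    charge,
                    [(f, assigned[f]) for f in sorted(assigned, key=lambda f: mz[f])],
                )
            )
        for f in leftovers:
            raw.append((mz[f], 1, [(f, None)]))

    raw.sort(key=lambda t: t[0])
    empcpds = []
    for k, (_, charge, members) in enumerate(raw):
        sign = 1 if ion_table.mode == "pos" else -1
        rel_members: list[tuple[str, IonRelation | None]] = []
        for f, cell in members:
            rel = (
                IonRelation(
                    isotope_label=cell[0], adduct_label=cell[1],
                    charge=sign * charge, mass_offset=cell[2],
                )
                if cell
                else None
            )
            rel_members.append((fids[f], rel))
        e = EmpiricalCompound(
            empcpd_id=f"E{k:05d}",
            members=rel_members,
            charge_state_mode=ion_table.mode,
        )
        infer_neutral_mass(e, table, mz_tol_ppm=mz_tol_ppm)
        empcpds.append(e)
    return empcpds


def infer_neutral_mass(
    empcpd: EmpiricalCompound,
    table: FeatureTable,
    mz_tol_ppm: float = 5.0,
) -> float | None:
    """Back-calculate the neutral monoisotopic mass of an empirical compound.

    Each member with a known ion relation implies M = m/z * |z| - mass_offset;
    the result is the mean over members. Members with unknown ions contribute
    nothing; with no usable member the mass stays absent. If the per-member
    implied masses spread beyond the m/z tolerance the compound is flagged
    (the mean is still kept).
    """
    implied = []
    for fid, ion in empcpd.members:
        if ion is None:
            continue
        mz_obs = float(table.frame.loc[fid, "mz"])
        implied.append(mz_obs * abs(ion.charge) - ion.mass_offset)
    if not implied:
        empcpd.neutral_mass = None
        return None
    mass = float(np.mean(implied))
    if len(implied) > 1:
        spread = max(implied) - min(implied)
        if spread > mass * mz_tol_ppm * 1e-6:
            if "inconsistent_neutral_mass" not in empcpd.flags:
                empcpd.flags.append("inconsistent_neutral_mass")
    empcpd.neutral_mass = mass
    return mass
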