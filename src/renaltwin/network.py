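"""Arterial network description: geometry, wall mechanics, topology, terminals.

The network is a rooted tree of 1D vessel segments.  Interior vessels end in
junctions (any number of daughters); every leaf carries exactly one terminal
element — either a lumped R-C-R windkessel or a renal microvascular bed.

File dialect (YAML, hand-editable units):

    vessels:
      - {id, name, parent, length_mm, radius_mm, wall_thickness_mm,
         youngs_modulus_kPa, group?, generation?}
    terminals:
      - {vessel, R1, R2, C}                    # SI: Pa*s/m^3, m^3/Pa
      - {vessel, microvascular_bed: {...}}     # renal bed (SI resistances)
    inlet: {vessel, waveform_ref}

Geometry is converted to SI on load; the reference lumen radius is taken at
the diastolic pressure of the inflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .microcirculation import MicrovascularBed, NephronCircuit, bed_equivalent_resistance

__all__ = [
    "VesselSegment",
    "WindkesselTerminal",
    "ArterialNetwork",
    "NetworkError",
    "load_network",
    "write_network",
    "build_renal_tree",
    "attach_renal_trees",
    "scale_network",
    "reference_network_path",
    "DEFAULT_RENAL_GEOMETRY",
    "RENAL_GENERATIONS",
    "SCALE_PARAMETERS",
]

MM = 1.0e-3
KPA = 1.0e3

RENAL_GENERATIONS = ("main", "segmental", "interlobar", "arcuate")
SCALE_PARAMETERS = ("length", "lumen_radius", "youngs_modulus", "wall_thickness", "pvr", "pvc")


class NetworkError(ValueError):
    """Raised for topology or validation failures; names the offending vessel."""


@dataclass(frozen=True)
class VesselSegment:
    """One 1D vessel segment (SI units)."""

    id: str
    length: float  # m
    lumen_radius_ref: float  # m, at reference (diastolic) pressure
    wall_thickness: float  # m
    youngs_modulus: float  # Pa
    parent: str | None = None
    name: str = ""
    group: str = "systemic"  # systemic | renal_left | renal_right
    generation: str | None = None  # renal generation tag, None for systemic

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NetworkError(f"vessel {self.id!r}: length must be > 0")
        if not 0 < self.lumen_radius_ref < 0.05:
            raise NetworkError(f"vessel {self.id!r}: lumen radius out of range (0, 0.05) m")
        if self.wall_thickness <= 0:
            raise NetworkError(f"vessel {self.id!r}: wall thickness must be > 0")
        if self.youngs_modulus <= 0:
            raise NetworkError(f"vessel {self.id!r}: Young's modulus must be > 0")

    @property
    def reference_area(self) -> float:
        return math.pi * self.lumen_radius_ref**2


@dataclass(frozen=True)
class WindkesselTerminal:
    """Lumped R-C-R element representing the downstream vasculature."""

    id: str
    proximal_resistance: float  # Pa*s/m^3
    distal_resistance: float  # Pa*s/m^3
    compliance: float  # m^3/Pa

    def __post_init__(self) -> None:
        if min(self.proximal_resistance, self.distal_resistance, self.compliance) <= 0:
            raise NetworkError(f"terminal {self.id!r}: all R-C-R values must be > 0")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance


@dataclass
class ArterialNetwork:
    """A validated rooted tree of vessels with terminal elements."""

    vessels: dict[str, VesselSegment]
    terminals: dict[str, WindkesselTerminal | MicrovascularBed]
    inlet_vessel: str
    waveform_ref: str = "default_aortic"
    children: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.children = {vid: [] for vid in self.vessels}
        for v in self.vessels.values():
            if v.parent is not None:
                if v.parent not in self.vessels:
                    raise NetworkError(f"vessel {v.id!r}: unknown parent {v.parent!r}")
                self.children[v.parent].append(v.id)
        self.validate()

    # -- queries -------------------------------------------------------------

    def leaves(self) -> list[str]:
        return [vid for vid, kids in self.children.items() if not kids]

    def vessels_in_group(self, *groups: str) -> list[VesselSegment]:
        return [v for v in self.vessels.values() if v.group in groups]

    def renal_vessels(self, generation: str | None = None) -> list[VesselSegment]:
        out = [v for v in self.vessels.values() if v.group.startswith("renal")]
        if generation is not None:
            out = [v for v in out if v.generation == generation]
        return out

    def n_systemic(self) -> int:
        return sum(1 for v in self.vessels.values() if v.group == "systemic")

    def beds(self) -> dict[str, MicrovascularBed]:
        return {k: t for k, t in self.terminals.items() if isinstance(t, MicrovascularBed)}

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        if self.inlet_vessel not in self.vessels:
            raise NetworkError(f"inlet vessel {self.inlet_vessel!r} not in network")
        roots = [v.id for v in self.vessels.values() if v.parent is None]
        if roots != [self.inlet_vessel]:
            raise NetworkError(f"expected single root {self.inlet_vessel!r}, found {roots}")
        # reachability from the root rules out cycles among non-roots
        seen: set[str] = set()
        stack = [self.inlet_vessel]
        while stack:
            vid = stack.pop()
            if vid in seen:
                raise NetworkError(f"cycle detected at vessel {vid!r}")
            seen.add(vid)
            stack.extend(self.children[vid])
        unreachable = set(self.vessels) - seen
        if unreachable:
            raise NetworkError(
                f"vessels not reachable from the root (cycle or orphan): {sorted(unreachable)}"
            )
        for leaf in self.leaves():
            if leaf not in self.terminals:
                raise NetworkError(f"leaf vessel {leaf!r} has no terminal element")
        for tid in self.terminals:
            if tid not in self.vessels:
                raise NetworkError(f"terminal attached to unknown vessel {tid!r}")
            if self.children[tid]:
                raise NetworkError(f"terminal attached to non-leaf vessel {tid!r}")

    def summary(self) -> str:
        n_wk = sum(1 for t in self.terminals.values() if isinstance(t, WindkesselTerminal))
        n_bed = len(self.beds())
        return (
            f"{len(self.vessels)} vessels ({self.n_systemic()} systemic, "
            f"{len(self.renal_vessels())} renal), {n_wk} windkessel outlets, "
            f"{n_bed} microvascular beds, inlet {self.inlet_vessel!r}"
        )


# --- YAML I/O ----------------------------------------------------------------


def _bed_to_dict(bed: MicrovascularBed) -> dict:
    return {
        "interlobular_resistance": float(bed.interlobular_resistance),
        "nephron": {k: float(v) for k, v in bed.nephron.resistances.items()},
        "n_interlobular_per_arcuate": bed.n_interlobular_per_arcuate,
        "n_nephrons_per_interlobular": bed.n_nephrons_per_interlobular,
        "surviving_fraction": float(bed.surviving_fraction),
        "compliance": float(bed.compliance),
    }


def _bed_from_dict(d: dict) -> MicrovascularBed:
    return MicrovascularBed(
        interlobular_resistance=float(d["interlobular_resistance"]),
        nephron=NephronCircuit({k: float(v) for k, v in d["nephron"].items()}),
        n_interlobular_per_arcuate=int(d.get("n_interlobular_per_arcuate", 650)),
        n_nephrons_per_interlobular=int(d.get("n_nephrons_per_interlobular", 60)),
        surviving_fraction=float(d.get("surviving_fraction", 1.0)),
        compliance=float(d.get("compliance", 2.53e-11)),
    )


def load_network(path: str | Path) -> ArterialNetwork:
    """Load and validate a network file (mm/kPa dialect, converted to SI)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "vessels" not in doc or "inlet" not in doc:
        raise NetworkError(f"{path}: not a network file (missing 'vessels'/'inlet')")
    vessels: dict[str, VesselSegment] = {}
    for row in doc["vessels"]:
        vid = str(row["id"])
        if vid in vessels:
            raise NetworkError(f"duplicate vessel id {vid!r}")
        vessels[vid] = VesselSegment(
            id=vid,
            parent=row.get("parent"),
            name=row.get("name", vid),
            length=float(row["length_mm"]) * MM,
            lumen_radius_ref=float(row["radius_mm"]) * MM,
            wall_thickness=float(row["wall_thickness_mm"]) * MM,
            youngs_modulus=float(row["youngs_modulus_kPa"]) * KPA,
            group=row.get("group", "systemic"),
            generation=row.get("generation"),
        )
    terminals: dict[str, WindkesselTerminal | MicrovascularBed] = {}
    for row in doc.get("terminals", []):
        vid = str(row["vessel"])
        if "microvascular_bed" in row:
            terminals[vid] = _bed_from_dict(row["microvascular_bed"])
        else:
            terminals[vid] = WindkesselTerminal(
                id=vid,
                proximal_resistance=float(row["R1"]),
                distal_resistance=float(row["R2"]),
                compliance=float(row["C"]),
            )
    return ArterialNetwork(
        vessels=vessels,
        terminals=terminals,
        inlet_vessel=str(doc["inlet"]["vessel"]),
        waveform_ref=str(doc["inlet"].get("waveform_ref", "default_aortic")),
    )


def write_network(network: ArterialNetwork, path: str | Path) -> None:
    """Write the same dialect back; numbers keep full precision so a
    write/load round-trip is bit-exact."""
    rows = []
    for v in network.vessels.values():
        row = {
            "id": v.id,
            "name": v.name,
            "parent": v.parent,
            "length_mm": float(v.length / MM),
            "radius_mm": float(v.lumen_radius_ref / MM),
            "wall_thickness_mm": float(v.wall_thickness / MM),
            "youngs_modulus_kPa": float(v.youngs_modulus / KPA),
        }
        if v.group != "systemic":
            row["group"] = v.group
        if v.generation is not None:
            row["generation"] = v.generation
        rows.append(row)
    term_rows = []
    for vid, t in network.terminals.items():
        if isinstance(t, MicrovascularBed):
            term_rows.append({"vessel": vid, "microvascular_bed": _bed_to_dict(t)})
        else:
            term_rows.append(
                {"vessel": vid, "R1": float(t.proximal_resistance),
                 "R2": float(t.distal_resistance), "C": float(t.compliance)}
            )
    doc = {
        "vessels": rows,
        "terminals": term_rows,
        "inlet": {"vessel": network.inlet_vessel, "waveform_ref": network.waveform_ref},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)


def reference_network_path() -> Path:
    """Path of the packaged 75-vessel systemic reference network.

    The tree is a standard adult arterial network assembled from published
    segment tables; it is a documented substitute for bespoke dimensional
    data that is not publicly available.
    """
    return Path(__file__).parent / "data" / "systemic_75.yaml"


# --- renal tree builder ------------------------------------------------------

#: substitute renal-generation geometry (editable); lengths/radii chosen from
#: standard renal-anatomy conventions, wall properties to give muscular-artery
#: wave speeds.
DEFAULT_RENAL_GEOMETRY: dict[str, dict[str, float]] = {
    "main": {"length_mm": 40.0, "radius_mm": 2.75, "wall_thickness_mm": 0.41, "youngs_modulus_kPa": 800.0},
    "segmental": {"length_mm": 28.0, "radius_mm": 2.00, "wall_thickness_mm": 0.32, "youngs_modulus_kPa": 900.0},
    "interlobar": {"length_mm": 30.0, "radius_mm": 1.30, "wall_thickness_mm": 0.22, "youngs_modulus_kPa": 1000.0},
    "arcuate": {"length_mm": 12.0, "radius_mm": 0.85, "wall_thickness_mm": 0.15, "youngs_modulus_kPa": 1100.0},
}

_N_SEGMENTAL = 5
_N_INTERLOBAR_PER_SEGMENTAL = 2


def build_renal_tree(
    arcuate_count_per_interlobar: int = 2,
    base_geometry: dict[str, dict[str, float]] | None = None,
    side: str = "left",
    bed: MicrovascularBed | None = None,
) -> ArterialNetwork:
    """Build one kidney's arterial fragment: 1 main -> 5 segmental ->
    10 interlobar -> 2 arcuates each (20 by default), every arcuate leaf
    terminated by a microvascular bed."""
    geom = base_geometry or DEFAULT_RENAL_GEOMETRY
    missing = [g for g in RENAL_GENERATIONS if g not in geom]
    if missing:
        raise NetworkError(f"renal base geometry missing generations: {missing}")
    if arcuate_count_per_interlobar < 1:
        raise NetworkError("arcuate_count_per_interlobar must be >= 1")
    group = f"renal_{side}"
    pre = side[0].upper()

    def seg(vid: str, generation: str, par: str | None) -> VesselSegment:
        g = geom[generation]
        return VesselSegment(
            id=vid,
            parent=par,
            name=vid,
            length=g["length_mm"] * MM,
            lumen_radius_ref=g["radius_mm"] * MM,
            wall_thickness=g["wall_thickness_mm"] * MM,
            youngs_modulus=g["youngs_modulus_kPa"] * KPA,
            group=group,
            generation=generation,
        )

    vessels: dict[str, VesselSegment] = {}
    main_id = f"{pre}_renal_main"
    vessels[main_id] = seg(main_id, "main", None)
    terminals: dict[str, WindkesselTerminal | MicrovascularBed] = {}
    bed = bed if bed is not None else MicrovascularBed()
    for i in range(1, _N_SEGMENTAL + 1):
        sid = f"{pre}_renal_seg{i}"
        vessels[sid] = seg(sid, "segmental", main_id)
        for j in range(1, _N_INTERLOBAR_PER_SEGMENTAL + 1):
            iid = f"{pre}_renal_int{i}{j}"
            vessels[iid] = seg(iid, "interlobar", sid)
            for k in range(1, arcuate_count_per_interlobar + 1):
                aid = f"{pre}_renal_arc{i}{j}{k}"
                vessels[aid] = seg(aid, "arcuate", iid)
                terminals[aid] = bed
    # a fragment is a valid network in its own right
    return ArterialNetwork(vessels=vessels, terminals=terminals, inlet_vessel=main_id)


def attach_renal_trees(
    systemic: ArterialNetwork,
    stubs: tuple[str, str] = ("r_renal", "l_renal"),
    base_geometry: dict[str, dict[str, float]] | None = None,
    bed: MicrovascularBed | None = None,
) -> ArterialNetwork:
    """Replace the two renal windkessel outlets of the systemic tree by full
    renal fragments (36 vessels, 20 beds each)."""
    vessels = dict(systemic.vessels)
    terminals = dict(systemic.terminals)
    for stub, side in zip(stubs, ("right", "left")):
        if stub not in vessels:
            raise NetworkError(f"systemic tree has no renal stub {stub!r}")
        terminals.pop(stub, None)
        frag = build_renal_tree(base_geometry=base_geometry, side=side, bed=bed)
        for vid, v in frag.vessels.items():
            vessels[vid] = replace(v, parent=stub) if vid == frag.inlet_vessel else v
        terminals.update(frag.terminals)
    return ArterialNetwork(
        vessels=vessels,
        terminals=terminals,
        inlet_vessel=systemic.inlet_vessel,
        waveform_ref=systemic.waveform_ref,
    )


# --- uniform scaling ---------------------------------------------------------


def _scale_bed(bed: MicrovascularBed, pvr: float, pvc: float) -> MicrovascularBed:
    nephron = NephronCircuit({k: v * pvr for k, v in bed.nephron.resistances.items()})
    return replace(
        bed,
        interlobular_resistance=bed.interlobular_resistance * pvr,
        nephron=nephron,
        compliance=bed.compliance * pvc,
    )


def scale_network(
    network: ArterialNetwork, factors: dict[str, float], scope: str = "all"
) -> ArterialNetwork:
    """Return a new network with scoped vessels/terminals multiplied by the
    given factors (keys from SCALE_PARAMETERS; absent keys default to 1)."""
    if scope not in ("systemic", "renal", "all"):
        raise NetworkError(f"unknown scope {scope!r}")
    for key, val in factors.items():
        if key not in SCALE_PARAMETERS:
            raise NetworkError(f"unknown scale parameter {key!r}")
        if val <= 0:
            raise NetworkError(f"non-positive factor for {key!r}: {val}")
    f = {k: factors.get(k, 1.0) for k in SCALE_PARAMETERS}

    def in_scope(group: str) -> bool:
        if scope == "all":
            return True
        is_renal = group.startswith("renal")
        return is_renal if scope == "renal" else not is_renal

    vessels = {}
    for vid, v in network.vessels.items():
        if in_scope(v.group):
            v = replace(
                v,
                length=v.length * f["length"],
                lumen_radius_ref=v.lumen_radius_ref * f["lumen_radius"],
                youngs_modulus=v.youngs_modulus * f["youngs_modulus"],
                wall_thickness=v.wall_thickness * f["wall_thickness"],
            )
        vessels[vid] = v
    terminals: dict[str, WindkesselTerminal | MicrovascularBed] = {}
    for tid, t in network.terminals.items():
        if in_scope(network.vessels[tid].group):
            if isinstance(t, MicrovascularBed):
                t = _scale_bed(t, f["pvr"], f["pvc"])
            else:
                t = WindkesselTerminal(
                    id=t.id,
                    proximal_resistance=t.proximal_resistance * f["pvr"],
                    distal_resistance=t.distal_resistance * f["pvr"],
                    compliance=t.compliance * f["pvc"],
                )
        terminals[tid] = t
    return ArterialNetwork(
        vessels=vessels,
        terminals=terminals,
        inlet_vessel=network.inlet_vessel,
        waveform_ref=network.waveform_ref,
    )
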