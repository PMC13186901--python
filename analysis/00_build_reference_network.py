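"""Write the packaged reference arterial network to the package data dir.

The systemic tree (75 vessels, 29 R-C-R outlets) is assembled
programmatically in ``renaltwin.reference``; this script serialises it to
the YAML network dialect so that it ships as an editable fixture, and
reports the topology summary and a load/write round-trip check.
"""

from pathlib import Path

from renaltwin.network import load_network, write_network, attach_renal_trees
from renaltwin.reference import build_systemic_reference

OUT = Path(__file__).resolve().parents[1] / "src" / "renaltwin" / "data" / "systemic_75.yaml"


def main() -> None:
    net = build_systemic_reference()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    write_network(net, OUT)
    loaded = load_network(OUT)
    assert loaded.summary() == net.summary()
    for vid, v in net.vessels.items():
        w = loaded.vessels[vid]
        assert (v.length, v.lumen_radius_ref, v.wall_thickness, v.youngs_modulus) == (
            w.length, w.lumen_radius_ref, w.wall_thickness, w.youngs_modulus
        ), vid
    print(f"wrote {OUT}")
    print("systemic:", net.summary())
    print("full:    ", attach_renal_trees(net).summary())


if __name__ == "__main__":
    main()
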