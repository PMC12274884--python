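"""Serialization helpers for barcodes, persistence images, mixtures and
species presets."""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .topology import PersistenceBarcode, PersistenceImage, DiagramMixture
from .synthetic import SpeciesPreset, NeuriteSpec, Geometry, DiameterModel


def save_barcode_csv(pb: PersistenceBarcode, path) -> None:
    """One 'birth,death' row per bar."""
    lines = ["birth,death"] + [f"{b:.9g},{t:.9g}" for b, t in pb.bars]
    Path(path).write_text("\n".join(lines) + "\n")


def load_barcode_csv(path, filtration: str = "radial") -> PersistenceBarcode:
    rows = Path(path).read_text().strip().splitlines()[1:]
    bars = np.array([[float(v) for v in r.split(",")] for r in rows]) if rows else np.zeros((0, 2))
    return PersistenceBarcode(bars, filtration, Path(path).stem)


def save_population_barcodes(pbs, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, pb in enumerate(pbs):
        name = f"barcode_{i:04d}.csv"
        save_barcode_csv(pb, directory / name)
        manifest.append({"file": name, "filtration": pb.filtration, "source_id": pb.source_id})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_population_barcodes(directory) -> list:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [load_barcode_csv(directory / e["file"], e["filtration"]) for e in manifest]


def save_persistence_image(img: PersistenceImage, path) -> None:
    """Flat binary array plus a JSON header with grid metadata."""
    path = Path(path)
    img.image.astype(np.float64).tofile(path)
    header = {
        "bounds": list(img.bounds),
        "kernel_sigma": img.kernel_sigma,
        "resolution": img.resolution,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def load_persistence_image(path) -> PersistenceImage:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    res = header["resolution"]
    arr = np.fromfile(path, dtype=np.float64).reshape(res, res)
    return PersistenceImage(arr, tuple(header["bounds"]), header["kernel_sigma"], res)


def mixture_to_json(mix: DiagramMixture) -> str:
    return json.dumps(
        {
            "weights": mix.weights.tolist(),
            "means": mix.means.tolist(),
            "covariances": mix.covariances.tolist(),
            "regularized": mix.regularized,
        }
    )


def mixture_from_json(text: str) -> DiagramMixture:
    d = json.loads(text)
    return DiagramMixture(
        np.array(d["weights"]),
        np.array(d["means"]),
        np.array(d["covariances"]),
        d.get("regularized", False),
    )


def _neurite_spec_to_dict(spec: NeuriteSpec) -> dict:
    return {
        "mixture": {
            "weights": spec.mixture.weights.tolist(),
            "means": spec.mixture.means.tolist(),
            "covariances": spec.mixture.covariances.tolist(),
        },
        "bar_count_mean": spec.bar_count_mean,
        "bar_count_sd": spec.bar_count_sd,
        "n_trees": spec.n_trees,
        "min_bars": spec.min_bars,
    }


def _neurite_spec_from_dict(d: dict) -> NeuriteSpec:
    m = d["mixture"]
    return NeuriteSpec(
        mixture=DiagramMixture(
            np.array(m["weights"]), np.array(m["means"]), np.array(m["covariances"])
        ),
        bar_count_mean=d["bar_count_mean"],
        bar_count_sd=d["bar_count_sd"],
        n_trees=d.get("n_trees", 1),
        min_bars=d.get("min_bars", 2),
    )


def preset_to_dict(preset: SpeciesPreset) -> dict:
    return {
        "name": preset.name,
        "pc": {k: _neurite_spec_to_dict(v) for k, v in preset.pc.items()},
        "interneuron": {k: _neurite_spec_to_dict(v) for k, v in preset.interneuron.items()},
        "pc_fraction": preset.pc_fraction,
        "soma_radius": preset.soma_radius,
        "geometry": asdict(preset.geometry),
        "diameters": asdict(preset.diameters),
    }


def preset_from_dict(d: dict) -> SpeciesPreset:
    return SpeciesPreset(
        name=d["name"],
        pc={k: _neurite_spec_from_dict(v) for k, v in d["pc"].items()},
        interneuron={k: _neurite_spec_from_dict(v) for k, v in d["interneuron"].items()},
        pc_fraction=d.get("pc_fraction", 0.7),
        soma_radius=d.get("soma_radius", 8.0),
        geometry=Geometry(**d.get("geometry", {})),
        diameters=DiameterModel(**d.get("diameters", {})),
    )


def save_preset(preset: SpeciesPreset, path) -> None:
    Path(path).write_text(yaml.safe_dump(preset_to_dict(preset), sort_keys=False))


def load_preset(path) -> SpeciesPreset:
    return preset_from_dict(yaml.safe_load(Path(path).read_text()))
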