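"""TIFF interchange, simulation configs, and seed bookkeeping.

Volumes travel as multi-page 32-bit float TIFF stacks in ImageJ layout
(one page per z slice, axes z,y,x) with the voxel pitch carried in the
ImageJ resolution/spacing metadata; complex quantities (refractive
volumes, fields) as ``*_real.tif`` / ``*_imag.tif`` pairs.  Round trips
are bit-exact at float32.

All randomness of a run flows from one root seed through named
substreams so each module's draw is reproducible in isolation.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fields import PupilSpec, SourceSpec
from .grid import ComplexField, FluorophoreVolume, Grid3D, RefractiveVolume
from .psf import TileLayout

__all__ = [
    "write_volume_tiff",
    "read_volume_tiff",
    "write_refractive_volume",
    "read_refractive_volume",
    "write_field",
    "read_field",
    "SimulationConfig",
    "load_config",
    "seed_streams",
]


def write_volume_tiff(
    path: str | Path, data: np.ndarray, dx: float, dy: float, dz: float
) -> None:
    """Write a (nz, ny, nx) float volume as an ImageJ-compatible TIFF."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    tifffile.imwrite(
        str(path),
        data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def _pitch_from_tiff(tif: tifffile.TiffFile, path: Path) -> tuple[float, float, float]:
    page = tif.pages[0]
    dx = dy = dz = None
    meta = tif.imagej_metadata
    # resolution tags are only trusted alongside ImageJ metadata (our
    # writer always sets both); a bare TIFF needs the sidecar
    if meta:
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            dx = float(Fraction(xres[1], xres[0]))
            dy = float(Fraction(yres[1], yres[0]))
        except (KeyError, ZeroDivisionError):
            pass
        if "spacing" in meta:
            dz = float(meta["spacing"])
    if dx is None or dz is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            sc = json.loads(sidecar.read_text())
            dx = dx or sc.get("dx")
            dy = dy or sc.get("dy")
            dz = dz or sc.get("dz")
    if dx is None or dy is None or dz is None:
        raise ValueError(
            f"{path} carries no voxel pitch metadata; write a sidecar "
            f"'{path.name}.json' with keys dx, dy, dz (micrometers)"
        )
    return dx, dy, dz


def read_volume_tiff(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a float32 volume TIFF; returns (data[(z,y,x)], (dx, dy, dz))."""
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        if data.dtype != np.float32:
            raise ValueError(
                f"{path} has dtype {data.dtype}; convert to 32-bit float "
                "(e.g. ImageJ: Image > Type > 32-bit) before loading"
            )
        pitch = _pitch_from_tiff(tif, path)
    if data.ndim == 2:
        data = data[None]
    return data, pitch


def write_refractive_volume(base: str | Path, volume: RefractiveVolume) -> tuple[Path, Path]:
    """Write n(z,y,x) as a *_real/_imag TIFF pair; returns the two paths."""
    base = Path(base)
    g = volume.grid
    p_re = base.with_name(base.name + "_real.tif")
    p_im = base.with_name(base.name + "_imag.tif")
    write_volume_tiff(p_re, volume.n.real, g.dx, g.dy, g.dz)
    write_volume_tiff(p_im, volume.n.imag, g.dx, g.dy, g.dz)
    return p_re, p_im


def read_refractive_volume(base: str | Path, n_ambient: float = 1.33) -> RefractiveVolume:
    base = Path(base)
    re, pitch = read_volume_tiff(base.with_name(base.name + "_real.tif"))
    im, _ = read_volume_tiff(base.with_name(base.name + "_imag.tif"))
    nz, ny, nx = re.shape
    grid = Grid3D(nx=nx, ny=ny, nz=nz, dx=pitch[0], dy=pitch[1], dz=pitch[2])
    return RefractiveVolume(
        grid=grid, n=re.astype(np.float64) + 1j * im.astype(np.float64), n_ambient=n_ambient
    )


def write_field(base: str | Path, field: ComplexField) -> tuple[Path, Path]:
    """Persist a complex field as a real/imag TIFF pair with metadata."""
    base = Path(base)
    p_re = base.with_name(base.name + "_real.tif")
    p_im = base.with_name(base.name + "_imag.tif")
    for p, part in ((p_re, field.values.real), (p_im, field.values.imag)):
        tifffile.imwrite(
            str(p),
            part.astype(np.float32),
            imagej=True,
            resolution=(1.0 / field.dx, 1.0 / field.dy),
            metadata={"unit": "um", "axes": "YX"},
        )
    sidecar = base.with_name(base.name + "_field.json")
    sidecar.write_text(
        json.dumps(
            {
                "dx": field.dx,
                "dy": field.dy,
                "wavelength": field.wavelength,
                "z_position": field.z_position,
            }
        )
    )
    return p_re, p_im


def read_field(base: str | Path) -> ComplexField:
    base = Path(base)
    re = tifffile.imread(str(base.with_name(base.name + "_real.tif")))
    im = tifffile.imread(str(base.with_name(base.name + "_imag.tif")))
    meta = json.loads(base.with_name(base.name + "_field.json").read_text())
    return ComplexField(
        values=re.astype(np.float64) + 1j * im.astype(np.float64),
        dx=meta["dx"],
        dy=meta["dy"],
        wavelength=meta["wavelength"],
        z_position=meta.get("z_position", 0.0),
    )


# --------------------------------------------------------------------------
# configuration schema


class GridModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nx: int
    ny: int
    nz: int
    dx: float
    dy: float | None = None
    dz: float | None = None

    def build(self) -> Grid3D:
        return Grid3D(
            nx=self.nx,
            ny=self.ny,
            nz=self.nz,
            dx=self.dx,
            dy=self.dy if self.dy is not None else self.dx,
            dz=self.dz if self.dz is not None else self.dx,
        )


class PhantomModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["spheres", "coated_spheres", "embryo", "perlin", "test_chart"]
    n_ambient: float = 1.33
    # spheres
    spheres: list[dict] | None = None
    # perlin
    mean_n: float = 1.36
    amplitude: float = 0.03
    correlation_length: float = 1.0
    octaves: int = 1
    kappa: float = 0.0
    # embryo
    n_nuclei: int = 50
    # test chart
    bar_periods: list[int] = Field(default_factory=lambda: [4, 8, 16])


class IlluminationModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal[
        "plane_wave", "gaussian", "cylindrical_sheet", "bessel", "bessel_lattice"
    ] = "cylindrical_sheet"
    na: float = 0.1
    wavelength: float = 0.488
    inner_na: float = 0.0
    softness: float = 0.0

    def build(self, n0: float) -> SourceSpec:
        pupil = PupilSpec(
            na=self.na,
            wavelength=self.wavelength,
            n0=n0,
            inner_na=self.inner_na,
            softness=self.softness,
        )
        return SourceSpec(kind=self.kind, pupil=pupil)


class DetectionModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    na: float = 0.6
    wavelength: float = 0.52
    softness: float = 0.3

    def build(self, n0: float) -> PupilSpec:
        return PupilSpec(
            na=self.na, wavelength=self.wavelength, n0=n0, softness=self.softness
        )


class TilesModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nx: int = 4
    ny: int = 4
    size: int = 16
    guard_margin: int = 2

    def build(self) -> TileLayout:
        return TileLayout(
            tile_nx=self.nx, tile_ny=self.ny, tile_size=self.size, guard_margin=self.guard_margin
        )


class ScanModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    z_positions: list[float] | None = None
    z_start: float | None = None
    z_stop: float | None = None
    n: int | None = None

    def positions(self, grid: Grid3D) -> list[float]:
        if self.z_positions is not None:
            return list(self.z_positions)
        z0 = self.z_start if self.z_start is not None else grid.nz * grid.dz / 2
        z1 = self.z_stop if self.z_stop is not None else z0
        n = self.n or 1
        return list(np.linspace(z0, z1, n))


class SimulationConfig(BaseModel):
    """Schema-validated description of one simulation run.

    Unknown keys are rejected; the resolved config is written beside
    every run's outputs for provenance.
    """

    model_config = ConfigDict(extra="forbid")
    grid: GridModel
    phantom: PhantomModel
    illumination: IlluminationModel = IlluminationModel()
    detection: DetectionModel = DetectionModel()
    tiles: TilesModel = TilesModel()
    scan: ScanModel = ScanModel()
    seed: int = 0
    blend: Literal["nearest", "bilinear"] = "bilinear"
    output_dir: str = "."

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SimulationConfig.model_validate(raw)


def seed_streams(root_seed: int) -> dict[str, np.random.Generator]:
    """Named, independent substreams derived from one root seed."""
    names = ("phantom", "illumination", "ao", "noise")
    seqs = np.random.SeedSequence(root_seed).spawn(len(names))
    return {name: np.random.default_rng(seq) for name, seq in zip(names, seqs)}


def build_phantom(cfg: SimulationConfig):
    """Construct the phantom a config describes (seeded substream)."""
    from . import phantoms

    grid = cfg.grid.build()
    p = cfg.phantom
    seed = int(np.random.SeedSequence(cfg.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
    if p.kind in ("spheres", "coated_spheres"):
        specs = [phantoms.SphereSpec(**s) for s in (p.spheres or [])]
        return phantoms.make_spheres(grid, specs, n_ambient=p.n_ambient)
    if p.kind == "perlin":
        return phantoms.make_perlin_tissue(
            grid,
            mean_n=p.mean_n,
            amplitude=p.amplitude,
            correlation_length=p.correlation_length,
            octaves=p.octaves,
            seed=seed,
            n_ambient=p.n_ambient,
            kappa=p.kappa,
        )
    if p.kind == "embryo":
        return phantoms.make_embryo(grid, seed=seed, n_nuclei=p.n_nuclei, n_ambient=p.n_ambient)
    if p.kind == "test_chart":
        fluor = phantoms.make_test_chart(grid, bar_periods=tuple(p.bar_periods))
        n = np.full(grid.shape, p.n_ambient, dtype=np.complex128)
        return phantoms.Phantom(
            refractive=RefractiveVolume(grid=grid, n=n, n_ambient=p.n_ambient),
            fluor=fluor,
            truth={"kind": "test_chart"},
        )
    raise ValueError(f"unknown phantom kind {p.kind}")
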