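import numpy as np
import pytest

from voxelgram import phantom as ph
from voxelgram import pipeline as pl
from voxelgram.correct import BackgroundRegion
from voxelgram.rawio import ChannelImage, RunManifest


@pytest.fixture()
def manifest():
    return RunManifest(
        spot_size=80.0, scan_speed=320.0, acquisition_period=0.25,
        line_spacing=80.0, section_interval=90.0,
        isotopes=("31P", "56Fe"),
        standard_concentrations={"56Fe": 20.0})


def make_image(values, isotope="31P", units="CPS"):
    return ChannelImage(values=np.asarray(values, dtype=float),
                        isotope=isotope, units=units)


@pytest.fixture(scope="session")
def corrupted_phantom():
    """Default-condition phantom run shared by the expensive end-to-end
    checks: 24 sections of 128x128 px with mounting perturbations, drift,
    background, noise and spikes, reconstructed by the full pipeline."""
    spec = ph.PhantomSpec(seed=1)
    volume, labels = ph.make_volume(spec)
    sections, truth = ph.slice_and_corrupt(volume, labels, spec)
    raw = ph.sections_as_runs(sections, spec)
    bg = [BackgroundRegion(rect=tuple(r)) for r in ph.background_regions(spec)]
    grid, results = pl.reconstruct(
        raw, spec.manifest(), bg,
        [s["standards"] for s in sections],
        [s["mask_polygon"] for s in sections])
    return {"spec": spec, "truth": truth, "grid": grid, "results": results}
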