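import numpy as np
import pytest

from loopfold import afm, synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def render_molecule(kind, length_nm=105.0, radius_nm=None, persistence_nm=None,
                    rotation=0.3, offset=(500.0, 500.0), step_nm=2.0,
                    noise_sigma_nm=0.0, expected_length=None, seed=0):
    """Rasterize one molecule and run segmentation; returns its record."""
    spec = synthgen.ContourSpec(kind, length_nm, radius_nm=radius_nm,
                                persistence_nm=persistence_nm,
                                step_nm=step_nm, seed=seed)
    img_spec = synthgen.AFMImageSpec(
        molecules=[synthgen.PlacedMolecule(spec, offset, rotation)],
        noise_sigma_nm=noise_sigma_nm, seed=seed)
    img, _ = synthgen.rasterize_afm_image(img_spec)
    if noise_sigma_nm > 0:
        img = afm.level_rows(img)
    records = afm.segment_molecules(
        img, expected_length if expected_length is not None else length_nm)
    assert len(records) == 1
    return records[0]


def annulus_record(outer_px=6, hole_px_list=((3, 3),),
                   size=13, pixel_size=synthgen.DEFAULT_PIXEL_NM):
    """A synthetic disk mask with explicit hole pixels, as a MoleculeRecord."""
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = np.mgrid[:size, :size]
    mask[(rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= outer_px ** 2] = True
    for (dr, dc) in hole_px_list:
        mask[size // 2 + dr - 3, size // 2 + dc - 3] = False
    heights = np.where(mask, 0.5, 0.0)
    rec = afm.MoleculeRecord(
        label=1, mask=mask, heights=heights, origin_px=(0, 0),
        pixel_size_nm=pixel_size, expected_length_nm=105.0)
    rec.has_hole, rec.hole_area_px = afm._holes(mask)
    return rec
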