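import numpy as np
import pytest

import lungquant as lq


@pytest.fixture(scope="session")
def params():
    return lq.AcquisitionParams()


@pytest.fixture(scope="session")
def full_phantom():
    """Default-resolution phantom: geometry, concentration, noiseless render."""
    spec = lq.PhantomSpec(seed=1)
    geometry = lq.build_geometry(spec)
    conc = lq.assign_concentration(geometry)
    params = lq.AcquisitionParams(voxel_mm=spec.spacing)
    dataset = lq.render_mri(geometry, conc, params)
    return dataset


@pytest.fixture(scope="session")
def full_phantom_snr50(full_phantom):
    """Same anatomy re-imaged with noise giving peripheral SNR 50."""
    ds = full_phantom
    sd = lq.noise_sd_for_peripheral_snr(ds.geometry, ds.truth_concentration, ds.params, 50.0)
    return lq.render_mri(ds.geometry, ds.truth_concentration, ds.params, noise_sd=sd)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-resolution phantom (same physical thorax) for fast tests."""
    spec = lq.PhantomSpec(seed=3).with_resolution((96, 96, 72))
    geometry = lq.build_geometry(spec)
    conc = lq.assign_concentration(geometry)
    params = lq.AcquisitionParams(voxel_mm=spec.spacing)
    return lq.render_mri(geometry, conc, params)


@pytest.fixture()
def toy_concentration():
    """Tiny hand-built concentration result + labels for metric arithmetic.

    PER: 84 voxels at 1 mM, CER: 16 voxels at 1 mM, on a 1 mm grid, so
    Q(PER) = 0.084 umol and Q(CER) = 0.016 umol -> PDF = 84%.
    """
    shape = (10, 10, 10)
    labels = np.zeros(shape, dtype=np.int16)
    labels[0, :, :] = 1  # 100 TLV-only voxels
    flat = labels.reshape(-1)
    per_idx = np.flatnonzero(flat == 0)[:84]
    cer_idx = np.flatnonzero(flat == 0)[84:100]
    flat[per_idx] = 2
    flat[cer_idx] = 3
    labels = flat.reshape(shape)
    c = np.where(labels >= 2, 1.0, 0.0)
    spacing = (1.0, 1.0, 1.0)
    conc = lq.ConcentrationResult(
        c_map=lq.Volume3D(c, spacing),
        r1_post=lq.Volume3D(np.full(shape, 5.0), spacing),
        r1_pre=1.25,
        invalid_voxel_count=0,
        negative_clamped_count=0,
    )
    return conc, lq.RegionLabels(labels), spacing
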