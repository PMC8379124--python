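import pytest

from coroct import EnergySpec, PhantomSpec, render_phantom

NO_NOISE = {"kg70": 0.0, "kg120": 0.0}


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sigma_conventional=dict(NO_NOISE), seed=0)


@pytest.fixture(scope="session")
def noiseless_image(noiseless_spec):
    """Noiseless, PSF-blurred default render at 10.5 mg/mL, 55 keV."""
    return render_phantom(noiseless_spec, EnergySpec.vmi(55), 10.5, "kg70")


@pytest.fixture(scope="session")
def sharp_fine_image():
    """No blur, no noise, 0.05 mm grid: disks are near-ideal top-hats."""
    spec = PhantomSpec(
        pixel_spacing=0.05, psf_sigma=0.0, noise_sigma_conventional=dict(NO_NOISE)
    )
    return render_phantom(spec, EnergySpec.vmi(55), 10.5, "kg70")
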