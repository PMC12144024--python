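{
  "comment": "Reconstruction catalog: 14 OSEM-family and 6 BSREM methods. unfiltered_fwhm_mm is the emulated effective transaxial resolution of the unfiltered reconstruction; the effective resolution of filtered methods is the quadrature sum with the post-filter.",
  "reference": "TOF-PSF-3i16s-5mm",
  "methods": [
    {"name": "3i16s-10mm", "family": "OSEM", "tof": false, "psf": false, "iterations": 3, "subsets": 16, "filter_fwhm_mm": 10.0, "beta": null, "unfiltered_fwhm_mm": 7.65},
    {"name": "3i16s-7mm", "family": "OSEM", "tof": false, "psf": false, "iterations": 3, "subsets": 16, "filter_fwhm_mm": 7.0, "beta": null, "unfiltered_fwhm_mm": 7.65},
    {"name": "3i16s-5mm", "family": "OSEM", "tof": false, "psf": false, "iterations": 3, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 7.65},
    {"name": "3i16s-3mm", "family": "OSEM", "tof": false, "psf": false, "iterations": 3, "subsets": 16, "filter_fwhm_mm": 3.0, "beta": null, "unfiltered_fwhm_mm": 7.65},
    {"name": "TOF-3i16s-5mm", "family": "TOF-OSEM", "tof": true, "psf": false, "iterations": 3, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 6.87},
    {"name": "TOF-PSF-1i16s-5mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 1, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 7.24},
    {"name": "TOF-PSF-2i16s-5mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 2, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 6.50},
    {"name": "TOF-PSF-3i16s-5mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 3, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 5.77},
    {"name": "TOF-PSF-4i16s-5mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 4, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 5.59},
    {"name": "TOF-PSF-5i16s-5mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 5, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 5.53},
    {"name": "TOF-PSF-6i16s-5mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 6, "subsets": 16, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 5.46},
    {"name": "TOF-PSF-3i34s-5mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 3, "subsets": 34, "filter_fwhm_mm": 5.0, "beta": null, "unfiltered_fwhm_mm": 5.50},
    {"name": "TOF-PSF-3i16s-3mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 3, "subsets": 16, "filter_fwhm_mm": 3.0, "beta": null, "unfiltered_fwhm_mm": 5.77},
    {"name": "TOF-PSF-3i34s-3mm", "family": "TOF-PSF-OSEM", "tof": true, "psf": true, "iterations": 3, "subsets": 34, "filter_fwhm_mm": 3.0, "beta": null, "unfiltered_fwhm_mm": 5.50},
    {"name": "BSREM-b100", "family": "BSREM", "tof": true, "psf": true, "iterations": null, "subsets": null, "filter_fwhm_mm": 0.0, "beta": 100, "unfiltered_fwhm_mm": 5.5},
    {"name": "BSREM-b200", "family": "BSREM", "tof": true, "psf": true, "iterations": null, "subsets": null, "filter_fwhm_mm": 0.0, "beta": 200, "unfiltered_fwhm_mm": 5.7},
    {"name": "BSREM-b300", "family": "BSREM", "tof": true, "psf": true, "iterations": null, "subsets": null, "filter_fwhm_mm": 0.0, "beta": 300, "unfiltered_fwhm_mm": 5.9},
    {"name": "BSREM-b400", "family": "BSREM", "tof": true, "psf": true, "iterations": null, "subsets": null, "filter_fwhm_mm": 0.0, "beta": 400, "unfiltered_fwhm_mm": 6.15},
    {"name": "BSREM-b500", "family": "BSREM", "tof": true, "psf": true, "iterations": null, "subsets": null, "filter_fwhm_mm": 0.0, "beta": 500, "unfiltered_fwhm_mm": 6.35},
    {"name": "BSREM-b600", "family": "BSREM", "tof": true, "psf": true, "iterations": null, "subsets": null, "filter_fwhm_mm": 0.0, "beta": 600, "unfiltered_fwhm_mm": 6.6}
  ]
}
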