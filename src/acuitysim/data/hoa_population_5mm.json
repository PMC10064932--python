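{
  "description": "Synthetic stand-in for population-average higher-order Zernike coefficients of the adult human eye over a 5-mm pupil. Values are representative of published population means (positive spherical aberration dominant, near-zero mean coma and trefoil), not a reproduction of any specific dataset.",
  "indexing": "OSA/ANSI single index",
  "units": "micrometres",
  "pupil_diameter_mm": 5.0,
  "coefficients_um": {
    "6": 0.010,
    "7": -0.020,
    "8": 0.005,
    "9": 0.008,
    "12": 0.062
  }
}
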