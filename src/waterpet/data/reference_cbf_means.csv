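method,region,quantification,mean_cbf,sd_cbf
3i16s-10mm,WB,regional,0.48,0.13
3i16s-10mm,WB,voxelwise,0.49,0.12
3i16s-10mm,GM,regional,0.52,0.14
3i16s-10mm,GM,voxelwise,0.52,0.13
3i16s-10mm,CWM,regional,0.28,0.07
3i16s-10mm,CWM,voxelwise,0.28,0.06
3i16s-7mm,WB,regional,0.48,0.13
3i16s-7mm,WB,voxelwise,0.49,0.12
3i16s-7mm,GM,regional,0.53,0.14
3i16s-7mm,GM,voxelwise,0.54,0.13
3i16s-7mm,CWM,regional,0.26,0.06
3i16s-7mm,CWM,voxelwise,0.27,0.06
3i16s-5mm,WB,regional,0.49,0.13
3i16s-5mm,WB,voxelwise,0.50,0.12
3i16s-5mm,GM,regional,0.54,0.14
3i16s-5mm,GM,voxelwise,0.55,0.14
3i16s-5mm,CWM,regional,0.25,0.06
3i16s-5mm,CWM,voxelwise,0.26,0.06
3i16s-3mm,WB,regional,0.49,0.13
3i16s-3mm,WB,voxelwise,0.50,0.13
3i16s-3mm,GM,regional,0.55,0.15
3i16s-3mm,GM,voxelwise,0.56,0.14
3i16s-3mm,CWM,regional,0.25,0.06
3i16s-3mm,CWM,voxelwise,0.26,0.06
TOF-3i16s-5mm,WB,regional,0.48,0.13
TOF-3i16s-5mm,WB,voxelwise,0.49,0.12
TOF-3i16s-5mm,GM,regional,0.54,0.14
TOF-3i16s-5mm,GM,voxelwise,0.55,0.14
TOF-3i16s-5mm,CWM,regional,0.23,0.05
TOF-3i16s-5mm,CWM,voxelwise,0.23,0.05
TOF-PSF-1i16s-5mm,WB,regional,0.48,0.13
TOF-PSF-1i16s-5mm,WB,voxelwise,0.49,0.12
TOF-PSF-1i16s-5mm,GM,regional,0.53,0.14
TOF-PSF-1i16s-5mm,GM,voxelwise,0.54,0.13
TOF-PSF-1i16s-5mm,CWM,regional,0.26,0.06
TOF-PSF-1i16s-5mm,CWM,voxelwise,0.26,0.06
TOF-PSF-2i16s-5mm,WB,regional,0.48,0.13
TOF-PSF-2i16s-5mm,WB,voxelwise,0.49,0.12
TOF-PSF-2i16s-5mm,GM,regional,0.54,0.15
TOF-PSF-2i16s-5mm,GM,voxelwise,0.55,0.14
TOF-PSF-2i16s-5mm,CWM,regional,0.23,0.05
TOF-PSF-2i16s-5mm,CWM,voxelwise,0.23,0.05
TOF-PSF-3i16s-5mm,WB,regional,0.48,0.13
TOF-PSF-3i16s-5mm,WB,voxelwise,0.49,0.12
TOF-PSF-3i16s-5mm,GM,regional,0.55,0.15
TOF-PSF-3i16s-5mm,GM,voxelwise,0.56,0.14
TOF-PSF-3i16s-5mm,CWM,regional,0.22,0.05
TOF-PSF-3i16s-5mm,CWM,voxelwise,0.22,0.05
TOF-PSF-4i16s-5mm,WB,regional,0.48,0.13
TOF-PSF-4i16s-5mm,WB,voxelwise,0.50,0.12
TOF-PSF-4i16s-5mm,GM,regional,0.55,0.15
TOF-PSF-4i16s-5mm,GM,voxelwise,0.56,0.14
TOF-PSF-4i16s-5mm,CWM,regional,0.21,0.05
TOF-PSF-4i16s-5mm,CWM,voxelwise,0.22,0.05
TOF-PSF-5i16s-5mm,WB,regional,0.48,0.13
TOF-PSF-5i16s-5mm,WB,voxelwise,0.50,0.12
TOF-PSF-5i16s-5mm,GM,regional,0.55,0.15
TOF-PSF-5i16s-5mm,GM,voxelwise,0.56,0.14
TOF-PSF-5i16s-5mm,CWM,regional,0.21,0.05
TOF-PSF-5i16s-5mm,CWM,voxelwise,0.22,0.05
TOF-PSF-6i16s-5mm,WB,regional,0.48,0.13
TOF-PSF-6i16s-5mm,WB,voxelwise,0.50,0.12
TOF-PSF-6i16s-5mm,GM,regional,0.55,0.15
TOF-PSF-6i16s-5mm,GM,voxelwise,0.56,0.14
TOF-PSF-6i16s-5mm,CWM,regional,0.21,0.05
TOF-PSF-6i16s-5mm,CWM,voxelwise,0.22,0.05
TOF-PSF-3i34s-5mm,WB,regional,0.48,0.13
TOF-PSF-3i34s-5mm,WB,voxelwise,0.50,0.12
TOF-PSF-3i34s-5mm,GM,regional,0.55,0.15
TOF-PSF-3i34s-5mm,GM,voxelwise,0.57,0.14
TOF-PSF-3i34s-5mm,CWM,regional,0.21,0.05
TOF-PSF-3i34s-5mm,CWM,voxelwise,0.22,0.05
TOF-PSF-3i16s-3mm,WB,regional,0.48,0.13
TOF-PSF-3i16s-3mm,WB,voxelwise,0.50,0.12
TOF-PSF-3i16s-3mm,GM,regional,0.56,0.15
TOF-PSF-3i16s-3mm,GM,voxelwise,0.57,0.14
TOF-PSF-3i16s-3mm,CWM,regional,0.21,0.05
TOF-PSF-3i16s-3mm,CWM,voxelwise,0.22,0.05
TOF-PSF-3i34s-3mm,WB,regional,0.49,0.13
TOF-PSF-3i34s-3mm,WB,voxelwise,0.51,0.13
TOF-PSF-3i34s-3mm,GM,regional,0.56,0.15
TOF-PSF-3i34s-3mm,GM,voxelwise,0.58,0.15
TOF-PSF-3i34s-3mm,CWM,regional,0.21,0.05
TOF-PSF-3i34s-3mm,CWM,voxelwise,0.22,0.05
BSREM-b100,WB,regional,0.49,0.13
BSREM-b100,WB,voxelwise,0.54,0.13
BSREM-b100,GM,regional,0.57,0.15
BSREM-b100,GM,voxelwise,0.62,0.15
BSREM-b100,CWM,regional,0.20,0.05
BSREM-b100,CWM,voxelwise,0.23,0.05
BSREM-b200,WB,regional,0.49,0.13
BSREM-b200,WB,voxelwise,0.52,0.13
BSREM-b200,GM,regional,0.57,0.15
BSREM-b200,GM,voxelwise,0.60,0.15
BSREM-b200,CWM,regional,0.20,0.05
BSREM-b200,CWM,voxelwise,0.21,0.05
BSREM-b300,WB,regional,0.49,0.13
BSREM-b300,WB,voxelwise,0.51,0.13
BSREM-b300,GM,regional,0.57,0.15
BSREM-b300,GM,voxelwise,0.59,0.15
BSREM-b300,CWM,regional,0.20,0.05
BSREM-b300,CWM,voxelwise,0.21,0.05
BSREM-b400,WB,regional,0.49,0.13
BSREM-b400,WB,voxelwise,0.51,0.13
BSREM-b400,GM,regional,0.56,0.15
BSREM-b400,GM,voxelwise,0.58,0.14
BSREM-b400,CWM,regional,0.20,0.05
BSREM-b400,CWM,voxelwise,0.22,0.05
BSREM-b500,WB,regional,0.49,0.13
BSREM-b500,WB,voxelwise,0.51,0.13
BSREM-b500,GM,regional,0.56,0.15
BSREM-b500,GM,voxelwise,0.58,0.14
BSREM-b500,CWM,regional,0.21,0.05
BSREM-b500,CWM,voxelwise,0.22,0.05
BSREM-b600,WB,regional,0.49,0.13
BSREM-b600,WB,voxelwise,0.50,0.13
BSREM-b600,GM,regional,0.56,0.15
BSREM-b600,GM,voxelwise,0.57,0.14
BSREM-b600,CWM,regional,0.21,0.05
BSREM-b600,CWM,voxelwise,0.22,0.05
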