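phrase,polarity,expandable
acute cardiopulmonary abnormality,indicates_no_pneumonia,0
areas of pneumonia,indicates_pneumonia,1
clear lungs,indicates_no_pneumonia,0
evidence of acute cardiopulmonary disease,indicates_no_pneumonia,0
features of bacterial pneumonia,indicates_pneumonia,1
focal airspace consolidation,indicates_pneumonia,1
focal consolidation,indicates_pneumonia,1
focal pulmonary infiltrate,indicates_pneumonia,1
ground glass opacities,indicates_pneumonia,1
hyperinflation,indicates_no_pneumonia,0
lungs are clear,indicates_no_pneumonia,0
multifocal airspace disease,indicates_pneumonia,1
negative chest,indicates_no_pneumonia,0
no abnormality,indicates_no_pneumonia,0
no pleural effusion,indicates_no_pneumonia,0
normal chest radiograph,indicates_no_pneumonia,0
normal chest x-ray,indicates_no_pneumonia,0
patchy consolidation,indicates_pneumonia,1
perihilar opacities,indicates_pneumonia,1
pleural effusion,indicates_pneumonia,1
pneumonia,indicates_pneumonia,1
pneumonia cannot be excluded,hedged,0
reactive airway disease,indicates_no_pneumonia,0
viral bronchiolitis,indicates_no_pneumonia,0
within normal limits,indicates_no_pneumonia,0
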