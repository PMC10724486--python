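{
  "name": "PROMIS-Cancer-Anxiety (Chinese calibration)",
  "K": 5,
  "metric": "logistic, D=1",
  "items": [
    {"item_id": "EDANX27", "wording": "I felt something awful would happen.", "a": 4.05, "b": [-2.52, -1.12, 0.12, 1.21]},
    {"item_id": "EDANX53", "wording": "I felt uneasy.", "a": 5.16, "b": [-2.33, -1.13, 0.06, 1.34]},
    {"item_id": "EDANX05", "wording": "I felt anxious.", "a": 5.47, "b": [-2.29, -1.17, 0.05, 1.46]},
    {"item_id": "EDANX12", "wording": "I felt upset.", "a": 4.13, "b": [-2.68, -0.84, 0.33, 1.66]},
    {"item_id": "EDANX55", "wording": "I had difficulty calming down.", "a": 3.88, "b": [-2.31, -0.5, 0.71, 1.95]},
    {"item_id": "EDANX01", "wording": "I felt fearly.", "a": 4.9, "b": [-1.63, -0.3, 0.93, 2.01]},
    {"item_id": "EDANX02", "wording": "I felt frightened.", "a": 4.08, "b": [-1.75, -0.27, 1.04, 2.07]},
    {"item_id": "EDANX33", "wording": "I felt terrified.", "a": 4.37, "b": [-1.6, 0.04, 1.29, 2.13]},
    {"item_id": "EDANX08", "wording": "I was concerned about my mental health.", "a": 2.68, "b": [-1.55, 0.1, 1.58, 2.63]},
    {"item_id": "EDANX47", "wording": "I felt indecisive.", "a": 2.28, "b": [-2.01, -0.54, 1.06, 3.21]},
    {"item_id": "EDANX18", "wording": "I had sudden feelings of panic.", "a": 2.76, "b": [-1.81, -0.37, 1.06, 2.66]},
    {"item_id": "EDANX26", "wording": "I felt fidgety.", "a": 2.86, "b": [-1.92, -0.42, 0.98, 2.58]},
    {"item_id": "EDANX07", "wording": "I felt like I need help for my anxiety.", "a": 2.62, "b": [-1.48, 0.37, 1.63, 2.62]},
    {"item_id": "EDANX30", "wording": "I felt worried.", "a": 2.6, "b": [-2.87, -1.48, 0.1, 1.66]},
    {"item_id": "EDANX46", "wording": "I felt nervous.", "a": 3.39, "b": [-2.48, -1.52, 0.0, 1.38]},
    {"item_id": "EDANX51", "wording": "I had trouble relaxing.", "a": 3.66, "b": [-2.08, -0.98, 0.32, 1.67]},
    {"item_id": "EDANX54", "wording": "I felt tense.", "a": 2.87, "b": [-1.98, -0.49, 0.79, 2.3]},
    {"item_id": "EDANX41", "wording": "My worries overwhelmed me.", "a": 2.69, "b": [-1.72, 0.24, 1.39, 2.66]},
    {"item_id": "EDANX03", "wording": "It scared me when I felt nervous.", "a": 2.3, "b": [-2.43, -0.49, 0.89, 2.23]},
    {"item_id": "EDANX48", "wording": "Many situations made me worry.", "a": 3.32, "b": [-2.57, -1.59, -0.22, 1.28]},
    {"item_id": "EDANX09", "wording": "I had unpleasant thoughts that wouldn't leave my mind.", "a": 4.23, "b": [-2.42, -1.68, -0.33, 1.13]},
    {"item_id": "EDANX39", "wording": "I worried about dying.", "a": 2.37, "b": [-2.94, -1.67, -0.23, 0.88]},
    {"item_id": "EDANX40", "wording": "I found it hard to focus on anything other than my anxiety.", "a": 2.7, "b": [-1.55, 0.22, 1.57, 3.21]}
  ]
}
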