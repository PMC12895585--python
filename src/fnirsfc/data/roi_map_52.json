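{
 "description": "Channel -> ROI map for the standard 3x11 alternating-grid 52-channel frontotemporal layout. Editable configuration: any channel may be re-assigned to one of the six ROI labels.",
 "roi_map": {
  "1": "TL(R)",
  "2": "TL(R)",
  "3": "DLPFC(R)",
  "4": "DLPFC(R)",
  "5": "mPFC(R)",
  "6": "mPFC(L)",
  "7": "DLPFC(L)",
  "8": "DLPFC(L)",
  "9": "TL(L)",
  "10": "TL(L)",
  "11": "TL(R)",
  "12": "TL(R)",
  "13": "DLPFC(R)",
  "14": "DLPFC(R)",
  "15": "DLPFC(R)",
  "16": "mPFC(R)",
  "17": "DLPFC(L)",
  "18": "DLPFC(L)",
  "19": "DLPFC(L)",
  "20": "TL(L)",
  "21": "TL(L)",
  "22": "TL(R)",
  "23": "TL(R)",
  "24": "DLPFC(R)",
  "25": "DLPFC(R)",
  "26": "mPFC(R)",
  "27": "mPFC(L)",
  "28": "DLPFC(L)",
  "29": "DLPFC(L)",
  "30": "TL(L)",
  "31": "TL(L)",
  "32": "TL(R)",
  "33": "TL(R)",
  "34": "DLPFC(R)",
  "35": "DLPFC(R)",
  "36": "DLPFC(R)",
  "37": "mPFC(L)",
  "38": "DLPFC(L)",
  "39": "DLPFC(L)",
  "40": "DLPFC(L)",
  "41": "TL(L)",
  "42": "TL(L)",
  "43": "TL(R)",
  "44": "TL(R)",
  "45": "DLPFC(R)",
  "46": "DLPFC(R)",
  "47": "mPFC(R)",
  "48": "mPFC(L)",
  "49": "DLPFC(L)",
  "50": "DLPFC(L)",
  "51": "TL(L)",
  "52": "TL(L)"
 }
}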